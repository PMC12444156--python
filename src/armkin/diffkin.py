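"""Numerical differentiation of motion series; speed profiles and path length.

Derivatives use three-point Lagrange central differences on interior points
(second order, non-uniform spacing) and one-sided four-point stencils on the
two samples at each boundary.  The higher-order boundary treatment matters because
jerk is obtained by differentiating three times: boundary error compounds at
each pass, and a second-order edge stencil visibly biases the integrated
squared jerk used by the log-dimensionless-jerk metric.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

_DERIV_UNIT = {
    "mm": "mm/s",
    "mm/s": "mm/s^2",
    "mm/s^2": "mm/s^3",
    "deg": "deg/s",
    "deg/s": "deg/s^2",
}


@dataclass
class ScalarProfile:
    """A timestamped scalar series (speed, acceleration, joint angle, ...)."""

    times: np.ndarray
    values: np.ndarray
    unit: str = ""
    derivative_order: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Path3D:
    """A timestamped sequence of 3D positions in millimetres."""

    times: np.ndarray
    points: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape != (len(self.times), 3):
            raise ValueError("points must have shape (len(times), 3)")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def _fd_weights(nodes: np.ndarray, x0: float) -> np.ndarray:
    """First-derivative finite-difference weights at ``x0`` for given nodes.

    Solves the Vandermonde moment conditions sum_i w_i (x_i-x0)^k = k! δ_{k,1},
    exact for polynomials of degree < len(nodes).
    """
    z = np.asarray(nodes, dtype=float) - x0
    n = len(z)
    rhs = np.zeros(n)
    rhs[1] = 1.0
    return np.linalg.solve(np.vander(z, increasing=True).T, rhs)


def _derivative_once(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """d(values)/dt for a 1-D or (N, k) array on a strictly increasing grid."""
    n = len(times)
    if n < 2:
        raise ValueError("need at least 2 samples to differentiate")
    if not np.all(np.diff(times) > 0):
        raise ValueError("duplicate or decreasing timestamps")
    if n == 2:
        slope = (values[1] - values[0]) / (times[1] - times[0])
        return np.stack([slope, slope])
    d = np.gradient(values, times, axis=0, edge_order=2)
    if n >= 4:
        rows = ((0, slice(0, 4)), (1, slice(0, 4)), (n - 2, slice(n - 4, n)), (n - 1, slice(n - 4, n)))
        for row, sl in rows:
            w = _fd_weights(times[sl], times[row])
            d[row] = np.tensordot(w, values[sl], axes=(0, 0))
    return d


def differentiate(obj: ScalarProfile | Path3D, order: int = 1):
    """Differentiate a profile or 3D path ``order`` times (1, 2 or 3)."""
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    if len(obj) < order + 1:
        raise ValueError(f"need at least {order + 1} samples for order {order}")
    if isinstance(obj, Path3D):
        values = obj.points
        for _ in range(order):
            values = _derivative_once(obj.times, values)
        return Path3D(times=obj.times.copy(), points=values)
    values = obj.values
    unit = obj.unit
    for _ in range(order):
        values = _derivative_once(obj.times, values)
        unit = _DERIV_UNIT.get(unit, f"{unit}/s" if unit else "")
    return ScalarProfile(
        times=obj.times.copy(),
        values=values,
        unit=unit,
        derivative_order=obj.derivative_order + order,
    )


def speed_profile(path: Path3D) -> ScalarProfile:
    """Euclidean norm of the first derivative of position, in mm/s."""
    vel = differentiate(path, 1)
    return ScalarProfile(
        times=path.times.copy(),
        values=np.linalg.norm(vel.points, axis=1),
        unit="mm/s",
        derivative_order=1,
    )


def tangential_acceleration(speed: ScalarProfile) -> ScalarProfile:
    """Signed rate of change of the speed profile (mm/s^2)."""
    return differentiate(speed, 1)


def path_length(path: Path3D) -> float:
    """Total polyline length in mm: sum of consecutive point distances."""
    if len(path) < 2:
        raise ValueError("need at least 2 points for a path length")
    return float(np.linalg.norm(np.diff(path.points, axis=0), axis=1).sum())


def resample_uniform(profile: ScalarProfile, rate: float) -> ScalarProfile:
    """Linear interpolation onto a uniform grid spanning [first, last] time.

    Endpoints are preserved exactly; the actual rate is the closest one whose
    integer number of intervals spans the profile.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if len(profile) < 2:
        raise ValueError("need at least 2 samples to resample")
    t0, t1 = float(profile.times[0]), float(profile.times[-1])
    n = int(round((t1 - t0) * rate)) + 1
    if n < 2:
        raise ValueError("rate too low for the profile span")
    grid = np.linspace(t0, t1, n)
    return ScalarProfile(
        times=grid,
        values=np.interp(grid, profile.times, profile.values),
        unit=profile.unit,
        derivative_order=profile.derivative_order,
    )
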