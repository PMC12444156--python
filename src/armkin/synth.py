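"""Schema-conformant synthetic recordings with analytically known kinematics.

The canonical smooth reach is the minimum-jerk trajectory
``x(τ) = D (10τ³ − 15τ⁴ + 6τ⁵)``, τ = t/T, whose closed-form kinematics make
every metric in the library checkable: mean speed D/T, peak speed 1.875·D/T
at τ = 1/2, mean-to-peak ratio 8/15, time-to-peak 50%, a single velocity
peak, one acceleration zero crossing, hand-path ratio 1 on a straight line,
and log dimensionless jerk −ln 720.

``generate_reach`` moves the wrist along a (possibly composed) minimum-jerk
path and places the elbow by a rigid two-link arm chain (upper arm 300 mm,
forearm 280 mm) behind it; trunk and neck stay stationary.
``generate_angle_sweep`` scripts one joint angle through a sinusoid by
forward kinematics, giving a ground-truth range of motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import Recording

UPPER_ARM_MM = 300.0
FOREARM_MM = 280.0

#: Static torso landmarks of the synthetic subject (mm; +z up, +y forward).
NECK = np.array([0.0, 0.0, 1400.0])
TRUNK = np.array([0.0, 0.0, 1100.0])
SHOULDER = {"left": np.array([-200.0, 0.0, 1400.0]), "right": np.array([200.0, 0.0, 1400.0])}
#: Wrist start pose relative to the shoulder (slightly forward and below).
WRIST_START_OFFSET = np.array([0.0, 150.0, -100.0])

_MIRROR = np.array([-1.0, 1.0, 1.0])
_SWAP = {"LWR": "RWR", "RWR": "LWR", "LEL": "REL", "REL": "LEL", "LSH": "RSH", "RSH": "LSH", "TRK": "TRK", "NK": "NK"}


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic reach recording.

    ``amplitude`` (mm) and ``duration`` (s) describe each minimum-jerk
    submovement; ``submovement_offsets`` are onset times (s) relative to the
    segment start (default: onsets spaced 0.6·duration apart).  ``noise_sd``
    adds isotropic Gaussian marker jitter reproducible from ``seed``.
    """

    amplitude: float = 300.0
    duration: float = 1.0
    rate: float = 200.0
    direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    n_submovements: int = 1
    submovement_offsets: tuple[float, ...] | None = None
    noise_sd: float = 0.0
    seed: int = 0
    arm_side: str = "right"  # "left" | "right" | "both"
    n_iterations: int = 1
    rest_duration: float = 0.5
    rest_label: str = "rest"

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.duration <= 0 or self.rate <= 0:
            raise ValueError("amplitude, duration and rate must be positive")
        if self.n_submovements < 1 or self.n_iterations < 1:
            raise ValueError("n_submovements and n_iterations must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.arm_side not in ("left", "right", "both"):
            raise ValueError("arm_side must be 'left', 'right' or 'both'")
        offs = self.offsets()
        if len(offs) != self.n_submovements or any(b <= a for a, b in zip(offs, offs[1:])) or offs[0] < 0:
            raise ValueError("submovement offsets must be non-negative and increasing")

    def offsets(self) -> tuple[float, ...]:
        if self.submovement_offsets is not None:
            return tuple(float(o) for o in self.submovement_offsets)
        return tuple(0.6 * self.duration * j for j in range(self.n_submovements))


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form expected metric values for a noise-free synthetic reach.

    Analytic fields are filled for the single-submovement case; ``npv``
    additionally assumes temporally separated submovements.  ``targets`` maps
    each generated side to the wrist's final position.
    """

    movement_time: float
    mv: float | None = None
    pv: float | None = None
    velocity_ratio: float | None = None
    tpv_percent: float | None = None
    ldj: float | None = None
    npv: int | None = None
    hpr: float | None = None
    targets: dict = field(default_factory=dict)
    starts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["targets"] = {k: list(v) for k, v in self.targets.items()}
        d["starts"] = {k: list(v) for k, v in self.starts.items()}
        return d


def min_jerk_position(D: float, T: float, t) -> np.ndarray | float:
    """Minimum-jerk displacement at time t in [0, T]; 0 at onset, D at offset."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > T):
        raise ValueError("t outside [0, T]")
    tau = t_arr / T
    out = D * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    return out if out.ndim else float(out)


def _mj_clamped(D: float, T: float, t: np.ndarray) -> np.ndarray:
    tau = np.clip(np.asarray(t, dtype=float) / T, 0.0, 1.0)
    return D * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def _elbow_ik(shoulder: np.ndarray, wrist: np.ndarray) -> np.ndarray:
    """Two-link inverse kinematics: elbow positions for given wrist path.

    The elbow is placed in the plane spanned by the shoulder-wrist axis and
    the global down direction, below the shoulder-wrist line (natural pose).
    """
    dvec = wrist - shoulder
    d = np.linalg.norm(dvec, axis=-1)
    lo, hi = abs(UPPER_ARM_MM - FOREARM_MM), UPPER_ARM_MM + FOREARM_MM
    if np.any(d > hi - 1e-9) or np.any(d < lo + 1e-9):
        raise ValueError("wrist out of reach of the two-link arm chain")
    u = dvec / d[..., None]
    a = (UPPER_ARM_MM**2 - FOREARM_MM**2 + d**2) / (2 * d)
    h = np.sqrt(UPPER_ARM_MM**2 - a**2)
    ref = np.array([0.0, 0.0, -1.0])
    w = ref - (u @ ref)[..., None] * u
    wn = np.linalg.norm(w, axis=-1)
    vertical = wn < 1e-9
    if np.any(vertical):
        alt = np.array([0.0, -1.0, 0.0])
        w = np.where(vertical[..., None], alt - (u @ alt)[..., None] * u, w)
        wn = np.linalg.norm(w, axis=-1)
    w = w / wn[..., None]
    return shoulder + a[..., None] * u + h[..., None] * w


def generate_reach(spec: SynthSpec) -> tuple[Recording, GroundTruth]:
    """Generate a minimum-jerk reach recording plus its analytic ground truth.

    Each iteration is one movement segment (labelled "1", "2", ...) of
    ``n_submovements`` composed minimum-jerk displacements along
    ``direction``; a rest block (labelled ``rest_label``) returns the wrist
    to the start pose between iterations.  With ``arm_side='both'`` the left
    arm mirrors the right across the sagittal (x = 0) plane.
    """
    offs = spec.offsets()
    t_move = offs[-1] + spec.duration
    n_move = round(t_move * spec.rate)
    n_rest = round(spec.rest_duration * spec.rate)
    if n_move < 4:
        raise ValueError("movement block too short at this rate")

    local = np.arange(n_move) / spec.rate
    disp_move = sum(_mj_clamped(spec.amplitude, spec.duration, local - o) for o in offs)
    total = spec.n_submovements * spec.amplitude
    rest_local = np.arange(n_rest) / spec.rate
    disp_rest = total * (1.0 - _mj_clamped(1.0, spec.rest_duration, rest_local)) if n_rest else np.empty(0)

    disp = []
    labels = []
    for it in range(spec.n_iterations):
        disp.append(disp_move)
        labels.extend([str(it + 1)] * n_move)
        disp.append(disp_rest)
        labels.extend([spec.rest_label] * n_rest)
    disp = np.concatenate(disp)
    n = len(disp)
    times = np.arange(n) / spec.rate

    direction = np.asarray(spec.direction, dtype=float)
    dn = np.linalg.norm(direction)
    if dn < 1e-12:
        raise ValueError("direction must be a non-zero vector")
    direction = direction / dn

    sides = ("left", "right") if spec.arm_side == "both" else (spec.arm_side,)
    positions: dict[str, np.ndarray] = {
        "TRK": np.tile(TRUNK, (n, 1)),
        "NK": np.tile(NECK, (n, 1)),
    }
    truth_targets: dict[str, tuple] = {}
    truth_starts: dict[str, tuple] = {}
    for side in sides:
        mirror = _MIRROR if side == "left" else np.ones(3)
        sh = SHOULDER[side]
        start = sh + WRIST_START_OFFSET
        wrist = start + np.outer(disp, direction * mirror)
        elbow = _elbow_ik(sh, wrist)
        prefix = "L" if side == "left" else "R"
        positions[f"{prefix}WR"] = wrist
        positions[f"{prefix}EL"] = elbow
        positions[f"{prefix}SH"] = np.tile(sh, (n, 1))
        truth_targets[side] = tuple(start + total * direction * mirror)
        truth_starts[side] = tuple(start)

    # Missing side's landmarks are absent (single-sided recordings are valid
    # as long as one wrist triplet exists).
    targets = None
    if len(sides) == 1:
        targets = np.tile(np.asarray(truth_targets[sides[0]]), (n, 1))

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        for code in sorted(positions):
            positions[code] = positions[code] + rng.normal(0.0, spec.noise_sd, (n, 3))

    rec = Recording(
        timestamps=times,
        positions=positions,
        iteration_labels=np.asarray(labels, dtype=object),
        targets=targets,
        meta={"units": "mm", "source": "synthetic-reach", "sampling_rate": spec.rate},
    )

    mt = (n_move - 1) / spec.rate
    if spec.noise_sd == 0 and spec.n_submovements == 1:
        truth = GroundTruth(
            movement_time=mt,
            mv=spec.amplitude / spec.duration,
            pv=1.875 * spec.amplitude / spec.duration,
            velocity_ratio=8.0 / 15.0,
            tpv_percent=50.0,
            ldj=-math.log(720.0),
            npv=1,
            hpr=1.0,
            targets=truth_targets,
            starts=truth_starts,
        )
    else:
        truth = GroundTruth(
            movement_time=mt,
            npv=spec.n_submovements if spec.noise_sd == 0 else None,
            targets=truth_targets,
            starts=truth_starts,
        )
    return rec, truth


def generate_angle_sweep(
    joint: str,
    min_angle: float,
    max_angle: float,
    cycles: int = 1,
    rate: float = 100.0,
    cycle_duration: float = 2.0,
) -> Recording:
    """Script one joint angle through a sinusoid between two bounds (degrees).

    Landmark positions are computed by forward kinematics so the specified
    elbow or shoulder angle follows
    ``θ(t) = min + (max − min)(1 − cos(2π·cycles·t/T))/2`` while every other
    joint stays static; zero cycles give a constant angle.
    """
    if not 0 <= min_angle < max_angle <= 180:
        raise ValueError("require 0 <= min_angle < max_angle <= 180 degrees")
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    side, kind = joint.split("_")
    if side not in ("left", "right") or kind not in ("elbow", "shoulder"):
        raise ValueError(f"unknown joint {joint!r}")

    duration = cycle_duration * max(cycles, 1)
    n = round(duration * rate)
    times = np.arange(n) / rate
    if cycles == 0:
        theta = np.full(n, math.radians(min_angle))
    else:
        amp = math.radians(max_angle) - math.radians(min_angle)
        theta = math.radians(min_angle) + amp * (1 - np.cos(2 * np.pi * cycles * times / duration)) / 2

    positions: dict[str, np.ndarray] = {
        "TRK": np.tile(TRUNK, (n, 1)),
        "NK": np.tile(NECK, (n, 1)),
    }
    down = np.array([0.0, 0.0, -1.0])
    forward = np.array([0.0, 1.0, 0.0])
    for s in ("left", "right"):
        sh = SHOULDER[s]
        prefix = "L" if s == "left" else "R"
        positions[f"{prefix}SH"] = np.tile(sh, (n, 1))
        if s != side:
            el = sh + UPPER_ARM_MM * down
            positions[f"{prefix}EL"] = np.tile(el, (n, 1))
            positions[f"{prefix}WR"] = np.tile(el + FOREARM_MM * down, (n, 1))
            continue
        if kind == "elbow":
            el = np.tile(sh + UPPER_ARM_MM * down, (n, 1))
            fore_dir = np.cos(theta)[:, None] * down + np.sin(theta)[:, None] * forward
            wr = el + FOREARM_MM * fore_dir
        else:
            # Horizontal trunk direction (neck -> shoulder) is +-x; the arm
            # sweeps in the vertical plane through it.
            lateral = (sh - NECK) / np.linalg.norm(sh - NECK)
            arm_dir = np.cos(theta)[:, None] * lateral - np.sin(theta)[:, None] * np.array([0.0, 0.0, 1.0])
            el = sh + UPPER_ARM_MM * arm_dir
            wr = el + FOREARM_MM * arm_dir
        positions[f"{prefix}EL"] = el
        positions[f"{prefix}WR"] = wr

    return Recording(
        timestamps=times,
        positions=positions,
        iteration_labels=np.asarray(["1"] * n, dtype=object),
        meta={"units": "mm", "source": "synthetic-sweep", "sampling_rate": rate},
    )


def mirror_recording(rec: Recording) -> Recording:
    """Reflect a recording across the sagittal (x = 0) plane, swapping sides."""
    positions = {_SWAP[code]: xyz * _MIRROR for code, xyz in rec.positions.items()}
    return Recording(
        timestamps=rec.timestamps.copy(),
        positions=positions,
        iteration_labels=rec.iteration_labels.copy(),
        targets=None if rec.targets is None else rec.targets * _MIRROR,
        meta=dict(rec.meta),
    )
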