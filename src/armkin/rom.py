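"""Joint angles and range of motion for elbow and shoulder.

The elbow angle is measured between the upper-arm vector (shoulder → elbow)
and the forearm vector (elbow → wrist); 0° is a fully extended arm, 180°
fully folded.  The shoulder angle replicates a clinical goniometer reading:
a virtual trunk point is placed horizontally out from the shoulder along the
neck → shoulder direction, and the angle between the upper-arm vector and the
shoulder → trunk-point vector is reported.  Angles are in degrees; range of
motion (ROM) is the max-minus-min of an angle series over a segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffkin import ScalarProfile
from .io import Recording, Segment, estimate_neck

JOINTS = ("left_elbow", "right_elbow", "left_shoulder", "right_shoulder")

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class AngleSeries:
    """Per-frame joint angle in degrees, in [0, 180]."""

    times: np.ndarray
    angles: np.ndarray
    joint: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.times.shape != self.angles.shape:
            raise ValueError("times and angles must have equal length")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("non-finite angle")

    def as_profile(self) -> ScalarProfile:
        return ScalarProfile(times=self.times, values=self.angles, unit="deg")


@dataclass
class RomResult:
    """Range of motion of one joint: max minus min angle over a window."""

    joint: str
    rom: float
    min_angle: float
    max_angle: float
    series: AngleSeries


def _axis_index(up_axis) -> int:
    if isinstance(up_axis, str):
        try:
            return _AXIS_INDEX[up_axis.lower()]
        except KeyError:
            raise ValueError(f"unknown axis {up_axis!r}") from None
    if up_axis in (0, 1, 2):
        return int(up_axis)
    raise ValueError(f"unknown axis {up_axis!r}")


def _angle_deg(u: np.ndarray, v: np.ndarray, context: str = "") -> np.ndarray:
    """Angle(s) in degrees between vectors; supports (..., 3) stacks."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    bad = (nu < 1e-12) | (nv < 1e-12)
    if np.any(bad):
        frame = int(np.argmax(np.atleast_1d(bad)))
        where = f" at frame {frame}" if np.ndim(bad) else ""
        raise ValueError(f"zero-length vector{where}{': ' + context if context else ''}")
    cosang = np.sum(u * v, axis=-1) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def elbow_angle(shoulder, elbow, wrist) -> float:
    """Angle (degrees) between upper-arm and forearm vectors; 0° = extended."""
    shoulder, elbow, wrist = (np.asarray(p, dtype=float) for p in (shoulder, elbow, wrist))
    return float(_angle_deg(elbow - shoulder, wrist - elbow, "limb vectors"))


def virtual_trunk_point(neck, shoulder, offset: float = 100.0, up_axis="z", reverse: bool = False):
    """Place a trunk reference horizontally out from the shoulder.

    The point lies ``offset`` mm from the shoulder along the horizontal
    projection (component along ``up_axis`` removed) of the neck → shoulder
    direction, so it shares the shoulder's height.  ``reverse`` flips to the
    shoulder → neck direction.  The shoulder angle is independent of
    ``offset``; the parameter only matters for visualization/export.
    """
    neck = np.asarray(neck, dtype=float)
    shoulder = np.asarray(shoulder, dtype=float)
    k = _axis_index(up_axis)
    h = shoulder - neck
    if reverse:
        h = -h
    h = h.copy()
    h[..., k] = 0.0
    norm = np.linalg.norm(h, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("neck directly above/below shoulder: horizontal direction undefined")
    return shoulder + offset * h / norm


def shoulder_angle(shoulder, elbow, neck, up_axis="z", offset: float = 100.0, reverse: bool = False) -> float:
    """Angle (degrees) between the upper-arm vector and the trunk vector."""
    shoulder = np.asarray(shoulder, dtype=float)
    elbow = np.asarray(elbow, dtype=float)
    trunk_pt = virtual_trunk_point(neck, shoulder, offset, up_axis, reverse)
    return float(_angle_deg(elbow - shoulder, trunk_pt - shoulder, "shoulder geometry"))


def angle_series(rec: Recording, joint: str, up_axis="z", reverse_trunk: bool = False) -> AngleSeries:
    """Per-frame joint angle series for one of the four supported joints.

    The shoulder joints need a neck series; when the NK landmark is absent it
    is estimated as the shoulder midpoint.  Any degenerate frame (zero-length
    limb vector, undefined horizontal trunk direction) raises an error naming
    the frame — no silent interpolation.
    """
    if joint not in JOINTS:
        raise ValueError(f"unknown joint {joint!r}; expected one of {JOINTS}")
    side, kind = joint.split("_")
    prefix = "L" if side == "left" else "R"

    def get(code: str) -> np.ndarray:
        if code not in rec.positions:
            raise ValueError(f"joint {joint} requires landmark {code}")
        return rec.positions[code]

    if kind == "elbow":
        sh, el, wr = get(f"{prefix}SH"), get(f"{prefix}EL"), get(f"{prefix}WR")
        angles = _angle_deg(el - sh, wr - el, f"{joint} limb vectors")
    else:
        sh, el = get(f"{prefix}SH"), get(f"{prefix}EL")
        if "NK" in rec.positions:
            nk = rec.positions["NK"]
        else:
            nk = estimate_neck(rec).positions["NK"]
        k = _axis_index(up_axis)
        h = sh - nk
        if reverse_trunk:
            h = -h
        h = h.copy()
        h[:, k] = 0.0
        norms = np.linalg.norm(h, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError(
                f"degenerate trunk direction at frame {int(np.argmax(norms < 1e-12))}"
            )
        angles = _angle_deg(el - sh, h, f"{joint} geometry")
    return AngleSeries(times=rec.timestamps.copy(), angles=angles, joint=joint)


def rom_range(series: AngleSeries, seg: Segment | None = None) -> RomResult:
    """Range of motion (max - min angle, degrees) within a segment.

    With ``seg=None`` the whole series is used (task-level ROM).
    """
    if seg is None:
        times, angles = series.times, series.angles
    else:
        mask = (series.times >= seg.t0) & (series.times <= seg.t1)
        if not mask.any():
            raise ValueError("segment does not overlap the angle series")
        times, angles = series.times[mask], series.angles[mask]
    if len(angles) == 0:
        raise ValueError("empty angle series")
    lo, hi = float(np.min(angles)), float(np.max(angles))
    return RomResult(
        joint=series.joint,
        rom=hi - lo,
        min_angle=lo,
        max_angle=hi,
        series=AngleSeries(times=times, angles=angles, joint=series.joint),
    )
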