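"""Speed, efficiency, accuracy and control-strategy metrics.

All metrics operate on one pre-segmented movement iteration: a speed profile
or 3D end-effector path restricted to the segment, plus the segment's onset
t0 and offset t1 taken from the input labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffkin import Path3D, ScalarProfile, path_length
from .io import Segment


@dataclass(frozen=True)
class TargetSpec:
    """A designated 3D target location in millimetres."""

    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise ValueError("target position must be a finite 3D point")
        object.__setattr__(self, "position", tuple(float(v) for v in p))


@dataclass(frozen=True)
class MetricValue:
    """One metric outcome for a (segment, side) pair.

    ``value`` is None when the metric was skipped; ``skip_reason`` then says
    why (e.g. no target configured, degenerate geometry).
    """

    name: str
    segment: str
    side: str
    value: float | None
    unit: str
    skip_reason: str | None = None


def movement_time(seg: Segment) -> float:
    """Movement time MT = t1 - t0 in seconds."""
    return seg.t1 - seg.t0


def mean_velocity(profile: ScalarProfile) -> float:
    """Arithmetic mean of the instantaneous speed samples (mm/s)."""
    if len(profile) == 0:
        raise ValueError("empty speed profile")
    return float(np.mean(profile.values))


def peak_velocity(profile: ScalarProfile) -> float:
    """Maximum of the speed profile (mm/s)."""
    if len(profile) == 0:
        raise ValueError("empty speed profile")
    return float(np.max(profile.values))


def hand_path_ratio(path: Path3D) -> float:
    """Travelled path length over straight-line start-to-end distance.

    1.0 means a perfectly direct reach; larger values indicate detours,
    corrections or hesitations.  Undefined for a closed path.
    """
    chord = float(np.linalg.norm(path.points[-1] - path.points[0]))
    if chord < 1e-12:
        raise ValueError("undefined HPR for closed path (start equals end)")
    return path_length(path) / chord


def target_error(p_final, target: TargetSpec | np.ndarray) -> float:
    """Euclidean distance (mm) from the final end-effector position to the target."""
    p = np.asarray(p_final, dtype=float)
    q = np.asarray(target.position if isinstance(target, TargetSpec) else target, dtype=float)
    if p.shape != (3,) or q.shape != (3,):
        raise ValueError("points must be 3D")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(p - q))


def time_to_peak_velocity(profile: ScalarProfile, seg: Segment) -> float:
    """Time of the speed maximum as a percentage of segment duration.

    Ties at the maximum take the earliest sample, since the metric measures
    how early peak speed occurs.  Result is in [0, 100].
    """
    if seg.t1 <= seg.t0:
        raise ValueError("zero-duration segment")
    mask = (profile.times >= seg.t0) & (profile.times <= seg.t1)
    if not mask.any():
        raise ValueError("speed profile has no samples inside the segment")
    times = profile.times[mask]
    values = profile.values[mask]
    t_peak = float(times[int(np.argmax(values))])
    return 100.0 * (t_peak - seg.t0) / (seg.t1 - seg.t0)
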