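"""Full analysis pipeline: read → segment → per-segment per-side metrics → export.

``run_analysis`` computes, for every movement segment and every requested
side, the eleven metrics on the end-effector trajectory (movement time, mean
and peak velocity, velocity ratio, velocity-peak count, acceleration
zero-crossings, log dimensionless jerk, spectral arc length, time to peak
velocity, hand-path ratio and target error) plus elbow and shoulder range of
motion over the whole task.  Accuracy and efficiency metrics require a
configured target and are recorded as skipped otherwise; any per-segment
numeric failure is likewise recorded with its reason and the run continues —
clinical files contain imperfect iterations.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .diffkin import Path3D, differentiate, ScalarProfile, speed_profile
from .io import Recording, REST_LABELS, Segment, read_recording, split_segments
from .metrics import (
    MetricValue,
    hand_path_ratio,
    mean_velocity,
    movement_time,
    peak_velocity,
    target_error,
    time_to_peak_velocity,
)
from .rom import angle_series, rom_range
from .smoothness import (
    PeakParams,
    SparcParams,
    count_velocity_peaks,
    log_dimensionless_jerk,
    sparc,
    velocity_ratio,
    zero_crossings_accel,
)

log = logging.getLogger("armkin")

ALL_METRICS: tuple[str, ...] = (
    "movement_time",
    "mean_velocity",
    "peak_velocity",
    "velocity_ratio",
    "n_velocity_peaks",
    "accel_zero_crossings",
    "log_dimensionless_jerk",
    "sparc",
    "time_to_peak_velocity",
    "hand_path_ratio",
    "target_error",
)

#: Metrics that need a designated target (efficiency and accuracy domains).
TARGET_METRICS: frozenset[str] = frozenset({"hand_path_ratio", "target_error"})

METRIC_UNITS: dict[str, str] = {
    "movement_time": "s",
    "mean_velocity": "mm/s",
    "peak_velocity": "mm/s",
    "velocity_ratio": "",
    "n_velocity_peaks": "count",
    "accel_zero_crossings": "count",
    "log_dimensionless_jerk": "",
    "sparc": "",
    "time_to_peak_velocity": "%",
    "hand_path_ratio": "",
    "target_error": "mm",
}


@dataclass
class AnalysisConfig:
    """Everything one analysis run needs.

    ``input`` is a CSV path or an in-memory :class:`Recording`.  ``target``
    may be a single 3D point, a ``{"left": ..., "right": ...}`` mapping, or
    None to fall back on per-row target columns in the input (accuracy and
    efficiency metrics are skipped when no target resolves).
    ``end_effector`` defaults to the wrist of the analyzed side.
    """

    input: object
    mapping: object | None = None
    sides: tuple[str, ...] = ("left", "right")
    end_effector: str | Mapping[str, str] | None = None
    target: object | None = None
    metrics: tuple[str, ...] | None = None
    peak_params: PeakParams = field(default_factory=PeakParams)
    sparc_params: SparcParams = field(default_factory=SparcParams)
    up_axis: str = "z"
    unit_scale: float = 1.0
    rest_labels: frozenset[str] = REST_LABELS
    reverse_trunk: bool = False

    def __post_init__(self) -> None:
        if self.metrics is not None:
            unknown = set(self.metrics) - set(ALL_METRICS)
            if unknown:
                raise ValueError(f"unknown metrics: {sorted(unknown)}")
            self.metrics = tuple(self.metrics)
        for side in self.sides:
            if side not in ("left", "right"):
                raise ValueError(f"unknown side {side!r}")


@dataclass
class RomEntry:
    """Task-level range of motion of one joint on one side."""

    joint: str
    side: str
    rom: float | None
    min_angle: float | None = None
    max_angle: float | None = None
    skip_reason: str | None = None


@dataclass
class MetricReport:
    """All metric values of one run plus provenance (config echo, version)."""

    values: list[MetricValue]
    rom: list[RomEntry]
    provenance: dict

    def value(self, name: str, segment: str, side: str) -> MetricValue:
        for mv in self.values:
            if mv.name == name and mv.segment == segment and mv.side == side:
                return mv
        raise KeyError((name, segment, side))


def _resolve_target(config: AnalysisConfig, rec: Recording, seg: Segment, side: str):
    tgt = config.target
    if isinstance(tgt, Mapping):
        tgt = tgt.get(side)
    if tgt is not None:
        return np.asarray(tgt, dtype=float)
    if rec.targets is not None:
        return rec.targets[seg.stop - 1]
    return None


def _resolve_end_effector(config: AnalysisConfig, side: str) -> str:
    ee = config.end_effector
    if isinstance(ee, Mapping):
        ee = ee.get(side)
    if ee is None:
        ee = "LWR" if side == "left" else "RWR"
    return ee


def _segment_metrics(
    config: AnalysisConfig, rec: Recording, seg: Segment, side: str, selected: Sequence[str]
) -> list[MetricValue]:
    out: list[MetricValue] = []
    ee = _resolve_end_effector(config, side)

    def emit(name, value=None, reason=None):
        out.append(
            MetricValue(
                name=name,
                segment=seg.label,
                side=side,
                value=None if reason else float(value),
                unit=METRIC_UNITS[name],
                skip_reason=reason,
            )
        )

    if ee not in rec.positions:
        for name in selected:
            emit(name, reason=f"end-effector landmark {ee} absent")
        return out

    path = Path3D(
        times=rec.timestamps[seg.start : seg.stop],
        points=rec.positions[ee][seg.start : seg.stop],
    )
    speed = accel_interior = None
    try:
        speed = speed_profile(path)
        tacc = differentiate(speed, 1)
        # One-sided boundary estimates of a near-zero endpoint acceleration
        # carry arbitrary sign; crossings are counted on interior samples.
        if len(tacc) > 3:
            accel_interior = ScalarProfile(
                times=tacc.times[1:-1], values=tacc.values[1:-1], unit=tacc.unit, derivative_order=2
            )
    except ValueError as exc:
        speed_err = str(exc)
        for name in selected:
            if name == "movement_time":
                emit(name, movement_time(seg))
            else:
                emit(name, reason=speed_err)
        return out

    target = _resolve_target(config, rec, seg, side)
    for name in selected:
        try:
            if name in TARGET_METRICS and target is None:
                emit(name, reason="no target configured")
            elif name == "movement_time":
                emit(name, movement_time(seg))
            elif name == "mean_velocity":
                emit(name, mean_velocity(speed))
            elif name == "peak_velocity":
                emit(name, peak_velocity(speed))
            elif name == "velocity_ratio":
                emit(name, velocity_ratio(speed))
            elif name == "n_velocity_peaks":
                emit(name, count_velocity_peaks(speed, config.peak_params))
            elif name == "accel_zero_crossings":
                if accel_interior is None:
                    emit(name, reason="segment too short for interior acceleration")
                else:
                    emit(name, zero_crossings_accel(accel_interior))
            elif name == "log_dimensionless_jerk":
                emit(name, log_dimensionless_jerk(path))
            elif name == "sparc":
                emit(name, sparc(speed, config.sparc_params))
            elif name == "time_to_peak_velocity":
                emit(name, time_to_peak_velocity(speed, seg))
            elif name == "hand_path_ratio":
                emit(name, hand_path_ratio(path))
            elif name == "target_error":
                emit(name, target_error(path.points[-1], target))
        except ValueError as exc:
            emit(name, reason=str(exc))
            log.warning("segment %s side %s: %s skipped: %s", seg.label, side, name, exc)
    return out


def run_analysis(config: AnalysisConfig) -> MetricReport:
    """Run the full pipeline and return a :class:`MetricReport`."""
    if isinstance(config.input, Recording):
        rec = config.input
    else:
        rec = read_recording(config.input, mapping=config.mapping, unit_scale=config.unit_scale)
    segments = split_segments(rec, config.rest_labels)
    selected = config.metrics if config.metrics is not None else ALL_METRICS
    log.info("analyzing %d segments on sides %s", len(segments), ",".join(config.sides))

    values: list[MetricValue] = []
    for side in config.sides:
        for seg in segments:
            values.extend(_segment_metrics(config, rec, seg, side, selected))

    rom_entries: list[RomEntry] = []
    for side in config.sides:
        for kind in ("elbow", "shoulder"):
            joint = f"{side}_{kind}"
            try:
                series = angle_series(rec, joint, config.up_axis, config.reverse_trunk)
                rr = rom_range(series)
                rom_entries.append(
                    RomEntry(joint=joint, side=side, rom=rr.rom, min_angle=rr.min_angle, max_angle=rr.max_angle)
                )
            except ValueError as exc:
                rom_entries.append(RomEntry(joint=joint, side=side, rom=None, skip_reason=str(exc)))
                log.warning("ROM %s skipped: %s", joint, exc)

    provenance = {
        "tool": "armkin",
        "version": __version__,
        "source": rec.meta.get("source", ""),
        "n_frames": rec.n_frames,
        "n_segments": len(segments),
        "time_range": [float(rec.timestamps[0]), float(rec.timestamps[-1])] if rec.n_frames else [],
        "config": {
            "sides": list(config.sides),
            "metrics": list(selected),
            "peak_params": {"delta": config.peak_params.delta, "tau": config.peak_params.tau},
            "sparc_params": {
                "omega_c": config.sparc_params.omega_c,
                "pad_level": config.sparc_params.pad_level,
                "amp_threshold": config.sparc_params.amp_threshold,
            },
            "up_axis": str(config.up_axis),
            "unit_scale": config.unit_scale,
        },
    }
    return MetricReport(values=values, rom=rom_entries, provenance=provenance)


def export_report(report: MetricReport, format: str, path) -> None:
    """Write a report as nested JSON or tidy long-format CSV."""
    if format == "json":
        nested: dict = {"provenance": report.provenance, "metrics": {}, "rom": {}}
        for mv in report.values:
            nested["metrics"].setdefault(mv.segment, {}).setdefault(mv.side, {})[mv.name] = {
                "value": mv.value,
                "unit": mv.unit,
                "skip_reason": mv.skip_reason,
            }
        for re_ in report.rom:
            nested["rom"].setdefault(re_.side, {})[re_.joint] = {
                "rom": re_.rom,
                "min_angle": re_.min_angle,
                "max_angle": re_.max_angle,
                "unit": "deg",
                "skip_reason": re_.skip_reason,
            }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(nested, fh, indent=2)
            fh.write("\n")
    elif format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["segment", "side", "metric", "value", "unit", "skip_reason"])
            for mv in report.values:
                writer.writerow(
                    [mv.segment, mv.side, mv.name, "" if mv.value is None else repr(mv.value), mv.unit, mv.skip_reason or ""]
                )
            for re_ in report.rom:
                kind = re_.joint.split("_")[1]
                writer.writerow(
                    ["all", re_.side, f"{kind}_rom", "" if re_.rom is None else repr(re_.rom), "deg", re_.skip_reason or ""]
                )
    else:
        raise ValueError(f"unknown export format {format!r} (expected 'json' or 'csv')")
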