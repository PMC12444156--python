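"""Reading, validating, writing and segmenting the canonical marker-CSV schema.

A recording is a CSV table with a ``timestamp`` column (UNIX seconds, strictly
increasing), an ``iteration`` column labelling movement repetitions (a
distinguished rest token separates them), and one ``<code>x/<code>y/<code>z``
coordinate triplet (millimetres) per tracked landmark.  Eight landmark codes
exist: left/right wrist (LWR/RWR), elbow (LEL/REL), shoulder (LSH/RSH), the
trunk (TRK) and the neck (NK).  The neck is optional and can be estimated from
the shoulders when absent.  Optional ``target_x/target_y/target_z`` columns
carry a per-row target position for accuracy/efficiency metrics.

Other column dialects are adapted through a JSON column mapping of the form
``{"timestamp": "...", "iteration": "...", "RWR": ["colx", "coly", "colz"]}``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LANDMARKS: tuple[str, ...] = ("LWR", "RWR", "LEL", "REL", "LSH", "RSH", "TRK", "NK")
OPTIONAL_LANDMARKS: tuple[str, ...] = ("NK",)
AXES: tuple[str, ...] = ("x", "y", "z")
TARGET_COLUMNS: tuple[str, ...] = ("target_x", "target_y", "target_z")

#: Iteration tokens that mark rows belonging to no movement segment.
REST_LABELS: frozenset[str] = frozenset({"", "rest"})


@dataclass(frozen=True)
class SchemaIssue:
    """One validation finding; ``error`` severity blocks analysis."""

    severity: str  # "error" | "warning"
    column: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.column}: {self.message}"


class SchemaError(ValueError):
    """Raised when a table cannot be read as a valid recording."""

    def __init__(self, issues: Sequence[SchemaIssue]):
        self.issues = list(issues)
        super().__init__("; ".join(str(i) for i in self.issues))


@dataclass(frozen=True)
class Segment:
    """One movement iteration: a maximal run of identical non-rest labels.

    ``t0``/``t1`` are the first/last timestamps of the run (both inclusive);
    ``start``/``stop`` delimit the contiguous row range (``stop`` exclusive).
    """

    label: str
    t0: float
    t1: float
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.t1 < self.t0:
            raise ValueError(f"segment {self.label!r}: t1 < t0")
        if self.stop <= self.start:
            raise ValueError(f"segment {self.label!r}: empty row span")

    @property
    def row_span(self) -> range:
        return range(self.start, self.stop)


@dataclass
class Recording:
    """Timestamped per-landmark 3D position series plus iteration labels.

    Positions are in millimetres, timestamps in seconds (UNIX epoch).  All
    landmark series share the length of ``timestamps``, which is strictly
    increasing.
    """

    timestamps: np.ndarray
    positions: dict[str, np.ndarray]
    iteration_labels: np.ndarray
    targets: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be one-dimensional")
        n = len(self.timestamps)
        if n and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("non-monotonic timestamps")
        if not np.all(np.isfinite(self.timestamps)):
            raise ValueError("non-finite timestamp")
        for code, xyz in list(self.positions.items()):
            if code not in LANDMARKS:
                raise ValueError(f"unknown landmark code {code!r}")
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (n, 3):
                raise ValueError(f"landmark {code}: expected shape ({n}, 3), got {xyz.shape}")
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"landmark {code}: non-finite coordinate")
            self.positions[code] = xyz
        labels = np.asarray(
            ["" if _is_na(v) else str(v) for v in np.asarray(self.iteration_labels, dtype=object)],
            dtype=object,
        )
        if labels.shape != (n,):
            raise ValueError("iteration_labels must have one label per row")
        self.iteration_labels = labels
        if self.targets is not None:
            t = np.asarray(self.targets, dtype=float)
            if t.shape != (n, 3):
                raise ValueError(f"targets: expected shape ({n}, 3), got {t.shape}")
            self.targets = t

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def landmarks(self) -> tuple[str, ...]:
        return tuple(self.positions)

    def sampling_rate(self) -> float:
        """Median-interval sampling-rate estimate in Hz."""
        if self.n_frames < 2:
            raise ValueError("need at least two frames to estimate a sampling rate")
        return 1.0 / float(np.median(np.diff(self.timestamps)))


def _is_na(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def _load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, skipinitialspace=True)


def _apply_mapping(df: pd.DataFrame, mapping) -> pd.DataFrame:
    """Rename a dialect's columns to the canonical schema."""
    if mapping is None:
        return df
    if isinstance(mapping, (str, Path)):
        with open(mapping, encoding="utf-8") as fh:
            mapping = json.load(fh)
    rename: dict[str, str] = {}
    for key, val in mapping.items():
        if key in ("timestamp", "iteration"):
            rename[str(val)] = key
        elif key in LANDMARKS:
            cols = list(val)
            if len(cols) != 3:
                raise ValueError(f"mapping for {key} must list exactly three columns (x, y, z)")
            for col, axis in zip(cols, AXES):
                rename[str(col)] = f"{key}{axis}"
        elif key == "target":
            for col, canon in zip(val, TARGET_COLUMNS):
                rename[str(col)] = canon
        else:
            raise ValueError(f"unknown mapping key {key!r}")
    return df.rename(columns=rename)


def _collect_issues(df: pd.DataFrame) -> list[SchemaIssue]:
    issues: list[SchemaIssue] = []
    err = lambda col, msg: issues.append(SchemaIssue("error", col, msg))
    warn = lambda col, msg: issues.append(SchemaIssue("warning", col, msg))

    for col in ("timestamp", "iteration"):
        if col not in df.columns:
            err(col, "mandatory column missing")

    present = []
    for code in LANDMARKS:
        cols = [f"{code}{a}" for a in AXES]
        have = [c for c in cols if c in df.columns]
        if have and len(have) < 3:
            for c in cols:
                if c not in df.columns:
                    err(c, f"incomplete coordinate triplet for landmark {code}")
        elif len(have) == 3:
            present.append(code)
    if not ({"LWR", "RWR"} & set(present)):
        err("LWRx/RWRx", "at least one wrist landmark triplet is required")

    coord_cols = [f"{c}{a}" for c in present for a in AXES]
    coord_cols += [c for c in TARGET_COLUMNS if c in df.columns]
    for col in coord_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            err(col, f"non-numeric coordinate at row {int(bad.idxmax())}")
        elif vals.isna().any():
            err(col, f"missing coordinate at row {int(vals.isna().idxmax())}")
        elif not np.all(np.isfinite(vals.to_numpy())):
            err(col, "non-finite coordinate")

    if "timestamp" in df.columns:
        ts = pd.to_numeric(df["timestamp"], errors="coerce")
        if ts.isna().any():
            err("timestamp", f"non-numeric timestamp at row {int(ts.isna().idxmax())}")
        else:
            t = ts.to_numpy(dtype=float)
            dt = np.diff(t)
            if np.any(dt < 0):
                err("timestamp", "non-monotonic timestamps")
            elif np.any(dt == 0):
                warn("timestamp", "duplicated timestamp rows (first occurrence kept on read)")
            if len(dt) > 1:
                pos = dt[dt > 0]
                if len(pos) > 1 and np.std(pos) / np.mean(pos) > 0.01:
                    warn("timestamp", "sampling-interval jitter exceeds 1% of the median interval")
    return issues


def validate_schema(source, mapping=None) -> list[SchemaIssue]:
    """Validate a CSV path or DataFrame; empty error set iff it reads cleanly."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        try:
            df = _load_table(source)
        except Exception as exc:
            return [SchemaIssue("error", str(source), f"unreadable file: {exc}")]
    try:
        df = _apply_mapping(df, mapping)
    except (ValueError, OSError, json.JSONDecodeError) as exc:
        return [SchemaIssue("error", "mapping", str(exc))]
    return _collect_issues(df)


def read_recording(source, mapping=None, unit_scale: float = 1.0) -> Recording:
    """Read a marker CSV (or DataFrame) into a validated :class:`Recording`.

    Parameters
    ----------
    source:
        CSV file path or an in-memory DataFrame in (or mappable to) the
        canonical schema.
    mapping:
        Optional column mapping (dict or JSON file path) for other dialects.
    unit_scale:
        Multiplier applied to every coordinate, e.g. 1000 for metre-based
        input; positions are millimetres internally.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        src = "<dataframe>"
    else:
        df = _load_table(source)
        src = str(source)
    df = _apply_mapping(df, mapping)
    issues = _collect_issues(df)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise SchemaError(errors)

    df = df.sort_values("timestamp", kind="stable")
    df = df[~df["timestamp"].astype(float).duplicated(keep="first")]
    ts = df["timestamp"].to_numpy(dtype=float)

    positions = {}
    for code in LANDMARKS:
        cols = [f"{code}{a}" for a in AXES]
        if all(c in df.columns for c in cols):
            positions[code] = df[list(cols)].to_numpy(dtype=float) * unit_scale
    targets = None
    if all(c in df.columns for c in TARGET_COLUMNS):
        targets = df[list(TARGET_COLUMNS)].to_numpy(dtype=float) * unit_scale

    dt = np.diff(ts)
    meta = {
        "units": "mm",
        "source": src,
        "sampling_rate": float(1.0 / np.median(dt)) if len(dt) else float("nan"),
    }
    return Recording(
        timestamps=ts,
        positions=positions,
        iteration_labels=df["iteration"].to_numpy(dtype=object),
        targets=targets,
        meta=meta,
    )


def estimate_neck(rec: Recording, overwrite: bool = False) -> Recording:
    """Return a copy with the neck series estimated as the shoulder midpoint.

    The neck marker is optional in the schema; when absent it is placed at the
    midpoint of the two shoulders, which fixes the horizontal neck-to-shoulder
    direction used by the shoulder-angle geometry for a level shoulder girdle.
    """
    for code in ("LSH", "RSH"):
        if code not in rec.positions:
            raise ValueError(f"neck estimation requires landmark {code}")
    if "NK" in rec.positions and not overwrite:
        raise ValueError("recording already has a neck series (pass overwrite=True)")
    positions = {c: p.copy() for c, p in rec.positions.items()}
    positions["NK"] = 0.5 * (rec.positions["LSH"] + rec.positions["RSH"])
    return Recording(
        timestamps=rec.timestamps.copy(),
        positions=positions,
        iteration_labels=rec.iteration_labels.copy(),
        targets=None if rec.targets is None else rec.targets.copy(),
        meta=dict(rec.meta, neck="estimated"),
    )


def split_segments(rec: Recording, rest_labels: Iterable[str] = REST_LABELS) -> list[Segment]:
    """Segment the recording into maximal runs of identical non-rest labels.

    Rest rows belong to no segment; a label value may recur later in the file
    and then opens a new segment.
    """
    rest = {str(r).strip().lower() for r in rest_labels}
    segments: list[Segment] = []
    idx = 0
    for label, group in itertools.groupby(rec.iteration_labels):
        n = sum(1 for _ in group)
        if str(label).strip().lower() not in rest:
            segments.append(
                Segment(
                    label=str(label),
                    t0=float(rec.timestamps[idx]),
                    t1=float(rec.timestamps[idx + n - 1]),
                    start=idx,
                    stop=idx + n,
                )
            )
        idx += n
    if not segments:
        raise ValueError("no movement iterations found")
    return segments


def write_recording(rec: Recording, path) -> None:
    """Write a Recording back to the canonical CSV schema (round-trip safe)."""
    if rec.n_frames == 0:
        raise ValueError("cannot write an empty recording")
    data: dict[str, np.ndarray] = {"timestamp": rec.timestamps, "iteration": rec.iteration_labels}
    for code in LANDMARKS:
        if code in rec.positions:
            for j, axis in enumerate(AXES):
                data[f"{code}{axis}"] = rec.positions[code][:, j]
    if rec.targets is not None:
        for j, col in enumerate(TARGET_COLUMNS):
            data[col] = rec.targets[:, j]
    pd.DataFrame(data).to_csv(path, index=False)
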