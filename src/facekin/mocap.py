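"""Reading and writing 3D marker-trajectory files and tidy feature tables.

Trajectory dialect
------------------
Wide tab-separated text, one row per frame::

    frame  time_s  <label>_X  <label>_Y  <label>_Z  ...

Coordinates are in millimetres, time in seconds. An empty field or a
literal ``NaN`` marks a missing coordinate; a frame is *invalid* for a
marker if any of its three coordinates is missing. Gaps are preserved as
gaps — nothing is ever interpolated on read or write.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError

__all__ = [
    "MarkerTrajectorySet",
    "read_trial",
    "write_trial",
    "read_feature_table",
    "write_feature_table",
    "read_manifest",
    "write_manifest",
    "read_vocal_table",
    "write_vocal_table",
]

#: Decimal places preserved by the trajectory writer (sub-micrometre).
COORD_DECIMALS = 6

_AXES = ("X", "Y", "Z")


@dataclass
class MarkerTrajectorySet:
    """Labeled per-marker 3D time series with a per-sample validity mask.

    Attributes
    ----------
    marker_labels : list of str
        Marker names, in file column order.
    time : ndarray, shape (n_frames,)
        Seconds from trial start; strictly increasing.
    coords : ndarray, shape (n_markers, n_frames, 3)
        Millimetres; NaN wherever ``valid`` is False.
    valid : ndarray of bool, shape (n_markers, n_frames)
        True where the marker was reconstructed at that frame.
    sample_rate : float
        Nominal capture rate in Hz.
    """

    marker_labels: list[str]
    time: np.ndarray
    coords: np.ndarray
    valid: np.ndarray
    sample_rate: float = 120.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        m, n = len(self.marker_labels), self.time.shape[0]
        if self.coords.shape != (m, n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} != ({m}, {n}, 3)"
            )
        if self.valid.shape != (m, n):
            raise ValueError(f"valid shape {self.valid.shape} != ({m}, {n})")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        # invalid samples carry no usable coordinates
        self.coords[~self.valid] = np.nan

    @property
    def n_frames(self) -> int:
        return self.time.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sample_rate

    def marker_index(self, label: str) -> int:
        try:
            return self.marker_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown marker label {label!r}") from None


def _parse_marker_columns(columns: list[str]) -> list[str]:
    """Validate `<label>_X/_Y/_Z` triples and return labels in order."""
    if len(columns) < 2 or columns[0] != "frame" or columns[1] != "time_s":
        raise FormatError(
            "trajectory header must start with 'frame\\ttime_s', "
            f"got {columns[:2]!r}"
        )
    rest = columns[2:]
    if len(rest) % 3 != 0:
        raise FormatError(
            f"marker columns do not form X/Y/Z triples: {len(rest)} columns"
        )
    labels: list[str] = []
    for i in range(0, len(rest), 3):
        triple = rest[i : i + 3]
        stems = {c.rsplit("_", 1)[0] for c in triple}
        axes = [c.rsplit("_", 1)[-1] for c in triple]
        if len(stems) != 1 or axes != list(_AXES):
            raise FormatError(
                f"malformed marker triple {triple!r}; expected "
                "<label>_X, <label>_Y, <label>_Z"
            )
        labels.append(triple[0].rsplit("_", 1)[0])
    if len(set(labels)) != len(labels):
        raise FormatError(f"duplicate marker labels in header: {labels!r}")
    return labels


def read_trial(path: str | Path, sample_rate: float = 120.0) -> MarkerTrajectorySet:
    """Read one trajectory file.

    Empty or NaN coordinate fields yield ``valid=False`` for that
    marker-frame; no interpolation is performed.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    columns = header.split("\t")
    labels = _parse_marker_columns(columns)
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NaN", "nan", ""])
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if list(df.columns) != columns:
        raise FormatError(f"{path}: inconsistent header")
    for col in columns:
        if len(df) and not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} at line {row}"
            )
    time = df["time_s"].to_numpy(dtype=float)
    if np.any(np.isnan(time)):
        raise FormatError(f"{path}: missing time value")
    if time.size > 1 and not np.all(np.diff(time) > 0):
        bad = int(np.flatnonzero(np.diff(time) <= 0)[0]) + 3
        raise FormatError(f"{path}: non-monotonic time at line {bad}")
    m, n = len(labels), len(df)
    coords = np.full((m, n, 3), np.nan)
    for k, label in enumerate(labels):
        for a, axis in enumerate(_AXES):
            coords[k, :, a] = df[f"{label}_{axis}"].to_numpy(dtype=float)
    valid = ~np.isnan(coords).any(axis=2)
    return MarkerTrajectorySet(labels, time, coords, valid, sample_rate)


def write_trial(traj: MarkerTrajectorySet, path: str | Path) -> None:
    """Write a trajectory set in the package dialect.

    Round trip through :func:`read_trial` reproduces coordinates to
    ``COORD_DECIMALS`` decimal places and the validity mask bit-exactly.
    """
    path = Path(path)
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(traj.n_frames),
        "time_s": traj.time,
    }
    for k, label in enumerate(traj.marker_labels):
        xyz = traj.coords[k].copy()
        xyz[~traj.valid[k]] = np.nan
        for a, axis in enumerate(_AXES):
            cols[f"{label}_{axis}"] = xyz[:, a]
    df = pd.DataFrame(cols)
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{COORD_DECIMALS}f",
              na_rep="")


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_feature_table(path: str | Path,
                       required: tuple[str, ...] = ("subject_id", "condition"),
                       ) -> pd.DataFrame:
    """Read a tidy per-trial feature CSV (subject_id, condition, numeric columns)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "condition": str})
    _require_columns(df, required, path)
    for col in df.columns:
        if col in ("subject_id", "condition", "kind", "path", "parameter"):
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at row {int(bad[0])}"
            )
        df[col] = parsed
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Trial manifest CSV: subject_id, condition, path (one row per trial)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ("subject_id", "condition", "path"), path)
    dup = df.duplicated(["subject_id", "condition"])
    if dup.any():
        pairs = df.loc[dup, ["subject_id", "condition"]].to_records(index=False)
        raise SchemaError(f"{path}: duplicate (subject, condition) pairs: {list(pairs)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_vocal_table(path: str | Path) -> pd.DataFrame:
    """Tidy vocal-parameter CSV: subject_id, condition, parameter, value."""
    df = pd.read_csv(path, dtype={"subject_id": str, "condition": str,
                                  "parameter": str})
    _require_columns(df, ("subject_id", "condition", "parameter", "value"), path)
    value = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[value.isna() & df["value"].notna()]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric vocal value at row {int(bad[0])}")
    df["value"] = value
    dup = df.duplicated(["subject_id", "condition", "parameter"])
    if dup.any():
        raise SchemaError(f"{path}: duplicate (subject, condition, parameter) rows")
    return df


def write_vocal_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def vocal_wide(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy vocal table to one row per (subject, condition)."""
    wide = df.pivot_table(index=["subject_id", "condition"], columns="parameter",
                          values="value", aggfunc="first")
    wide.columns.name = None
    return wide.reset_index()
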