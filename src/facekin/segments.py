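"""Facial-segment lengths from marker pairs.

A *segment* is the straight line between two facial markers; its
per-frame Euclidean length in 3D indexes expansion and contraction of
that part of the face. The default set spans four segments — vertical
brow raise, horizontal eyebrow spread, horizontal lip-corner spread, and
vertical jaw opening — plus four supplementary vertical segments from
the nose bridge to each inner eyebrow and each lip corner.

Frames where either marker of a pair is missing are dropped from the
trial mean, never interpolated: filling gaps would artificially shift
the mean the analysis is built on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedFeatureError
from .mocap import MarkerTrajectorySet

__all__ = [
    "SegmentSpec",
    "SegmentSeries",
    "TrialFeatures",
    "DEFAULT_MARKERS",
    "DEFAULT_SEGMENTS",
    "SUPPLEMENTARY_SEGMENTS",
    "segment_length_sample",
    "compute_segment_series",
    "mean_segment_length",
    "extract_trial_features",
]

#: The seven facial markers the default segment wiring assumes.
DEFAULT_MARKERS = (
    "mid_brow",
    "l_eyebrow",
    "r_eyebrow",
    "nose_bridge",
    "l_lip",
    "r_lip",
    "jaw",
)


@dataclass(frozen=True)
class SegmentSpec:
    """A named marker pair with its orientation and face region."""

    name: str
    marker_a: str
    marker_b: str
    orientation: str  # "vertical" | "horizontal"
    region: str  # "upper" | "lower"

    def __post_init__(self) -> None:
        if self.marker_a == self.marker_b:
            raise ConfigurationError(
                f"segment {self.name!r}: marker_a == marker_b ({self.marker_a!r})"
            )
        if self.orientation not in ("vertical", "horizontal"):
            raise ConfigurationError(
                f"segment {self.name!r}: orientation {self.orientation!r}"
            )
        if self.region not in ("upper", "lower"):
            raise ConfigurationError(f"segment {self.name!r}: region {self.region!r}")


# Default wiring. The source material shows the four segments graphically
# without printing the exact marker pairings, so these are documented
# conventions, overridable in configuration — not ground truth.
DEFAULT_SEGMENTS = (
    SegmentSpec("brow", "mid_brow", "nose_bridge", "vertical", "upper"),
    SegmentSpec("eyebrow", "l_eyebrow", "r_eyebrow", "horizontal", "upper"),
    SegmentSpec("lips", "l_lip", "r_lip", "horizontal", "lower"),
    SegmentSpec("jaw", "nose_bridge", "jaw", "vertical", "lower"),
)

#: Exploratory vertical segments: nose bridge to each inner eyebrow and
#: to each lip corner.
SUPPLEMENTARY_SEGMENTS = (
    SegmentSpec("v_eyebrow_l", "nose_bridge", "l_eyebrow", "vertical", "upper"),
    SegmentSpec("v_eyebrow_r", "nose_bridge", "r_eyebrow", "vertical", "upper"),
    SegmentSpec("v_lip_l", "nose_bridge", "l_lip", "vertical", "lower"),
    SegmentSpec("v_lip_r", "nose_bridge", "r_lip", "vertical", "lower"),
)


@dataclass
class SegmentSeries:
    """Per-frame Euclidean length of one segment over one trial."""

    spec: SegmentSpec
    length_mm: np.ndarray
    valid: np.ndarray
    sample_rate: float

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def coverage(self) -> float:
        return self.n_valid / self.valid.size if self.valid.size else 0.0


@dataclass
class TrialFeatures:
    """Per-trial mean segment lengths (mm) with coverage bookkeeping."""

    subject_id: str
    condition: str
    mean_length_mm: dict[str, float]
    n_valid: dict[str, int]
    coverage: dict[str, float]


def segment_length_sample(p_a, p_b) -> float:
    """Euclidean distance ``d`` between two 3D points in millimetres.

    d = sqrt((x2-x1)^2 + (y2-y1)^2 + (z2-z1)^2); symmetric in its
    arguments and invariant under any common rigid motion. Non-finite
    input returns NaN (an invalid sample).
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if not (np.all(np.isfinite(p_a)) and np.all(np.isfinite(p_b))):
        return float("nan")
    return float(np.sqrt(np.sum((p_b - p_a) ** 2)))


def compute_segment_series(traj: MarkerTrajectorySet, spec: SegmentSpec
                           ) -> SegmentSeries:
    """Per-frame length time series for one segment.

    A frame is valid for the segment iff *both* markers are valid there
    (AND rule); invalid frames carry NaN lengths and are omitted from
    downstream means.
    """
    try:
        ia = traj.marker_index(spec.marker_a)
        ib = traj.marker_index(spec.marker_b)
    except KeyError as exc:
        raise ConfigurationError(f"segment {spec.name!r}: {exc}") from exc
    valid = traj.valid[ia] & traj.valid[ib]
    diff = traj.coords[ib] - traj.coords[ia]
    with np.errstate(invalid="ignore"):
        length = np.sqrt(np.sum(diff * diff, axis=1))
    length[~valid] = np.nan
    return SegmentSeries(spec, length, valid, traj.sample_rate)


def mean_segment_length(series: SegmentSeries, min_valid: int = 1) -> float:
    """Trial-mean segment length Md in millimetres.

    Md is the mean of the per-frame lengths over the *valid* frames. On
    a gap-free trial this equals the textbook sum-over-frames divided by
    sample_rate x duration; with gaps the denominator is the number of
    valid frames, so omitted frames do not drag the mean toward zero.
    """
    n_valid = series.n_valid
    if n_valid < max(min_valid, 1):
        raise UndefinedFeatureError(
            series.spec.name,
            f"segment {series.spec.name!r}: {n_valid} valid frames "
            f"(minimum {max(min_valid, 1)})",
        )
    return float(np.nanmean(series.length_mm[series.valid]))


def extract_trial_features(
    traj: MarkerTrajectorySet,
    specs=DEFAULT_SEGMENTS,
    subject_id: str = "",
    condition: str = "",
    min_coverage: float = 0.5,
) -> TrialFeatures:
    """One mean length per segment spec for a single trial.

    ``min_coverage`` is the minimum fraction of frames that must be
    valid for a segment's mean to be defined (default 50%); a segment
    below it raises :class:`UndefinedFeatureError`.
    """
    specs = tuple(specs)
    if not specs:
        raise ConfigurationError("empty segment spec list")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate segment names: {names}")
    means, n_valid, coverage = {}, {}, {}
    for spec in specs:
        series = compute_segment_series(traj, spec)
        min_valid = int(np.ceil(min_coverage * traj.n_frames))
        means[spec.name] = mean_segment_length(series, min_valid=max(min_valid, 1))
        n_valid[spec.name] = series.n_valid
        coverage[spec.name] = series.coverage
    return TrialFeatures(subject_id, condition, means, n_valid, coverage)


def features_to_frame(features: list[TrialFeatures]) -> pd.DataFrame:
    """Stack per-trial features into a tidy wide table (one row per trial)."""
    rows = []
    for f in features:
        row: dict = {"subject_id": f.subject_id, "condition": f.condition}
        row.update(f.mean_length_mm)
        row.update({f"coverage_{k}": v for k, v in f.coverage.items()})
        rows.append(row)
    return pd.DataFrame(rows)
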