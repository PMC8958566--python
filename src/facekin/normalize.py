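"""Percent-change normalization against the neutral-speech baseline.

Expressive facial scores are confounded by two nuisance factors: the
articulatory movement required to speak the script at all, and the
overall size of the speaker's face. Both are removed by expressing each
trial's mean segment length as a percent change relative to the same
subject's neutral-emotion recitation of the same script:

    %change = 100 * (Md_performance - Md_neutral) / Md_neutral

Positive values mean expansion relative to neutral speech, negative
values contraction. The neutral condition itself maps to exactly zero
and is excluded from the univariate analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .errors import NormalizationError, SchemaError
from .segments import TrialFeatures

__all__ = [
    "percent_change",
    "normalize_cohort",
    "screen_outliers",
]

META_COLUMNS = ("subject_id", "condition", "kind", "path")


def percent_change(perf: TrialFeatures, neutral: TrialFeatures) -> dict[str, float]:
    """Per-segment percent change of one performance trial vs neutral."""
    if perf.subject_id != neutral.subject_id:
        raise NormalizationError(
            perf.subject_id, "*",
            f"baseline subject {neutral.subject_id!r} != {perf.subject_id!r}",
        )
    out: dict[str, float] = {}
    for seg, value in perf.mean_length_mm.items():
        base = neutral.mean_length_mm.get(seg)
        if base is None or not np.isfinite(base) or base <= 0:
            raise NormalizationError(perf.subject_id, seg)
        out[seg] = 100.0 * (value - base) / base
    return out


def _segment_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns
            if c not in META_COLUMNS and not c.startswith("coverage_")]


def normalize_cohort(features: pd.DataFrame, baseline_condition: str = "neutral",
                     ) -> pd.DataFrame:
    """Normalize a cohort feature table against each subject's baseline.

    Parameters
    ----------
    features : DataFrame
        One row per trial: subject_id, condition, one column per segment
        mean length in mm (coverage_* columns are ignored).
    baseline_condition : str
        Condition label of the within-subject baseline trial.

    Returns
    -------
    DataFrame with one row per non-baseline trial and percent-change
    columns in place of the raw means. Subjects lacking a baseline trial
    are reported together in a single aggregated error.
    """
    seg_cols = _segment_columns(features)
    if not seg_cols:
        raise SchemaError("feature table has no segment columns")
    missing = []
    for subject, grp in features.groupby("subject_id", sort=False):
        if not (grp["condition"] == baseline_condition).any():
            missing.append(str(subject))
    if missing:
        raise NormalizationError(
            ",".join(missing), "*",
            f"subjects missing a {baseline_condition!r} baseline trial: {missing}",
        )
    out_rows = []
    for subject, grp in features.groupby("subject_id", sort=False):
        base = grp.loc[grp["condition"] == baseline_condition, seg_cols].iloc[0]
        for seg in seg_cols:
            if not np.isfinite(base[seg]) or base[seg] <= 0:
                raise NormalizationError(str(subject), seg)
        perf = grp.loc[grp["condition"] != baseline_condition]
        pct = 100.0 * (perf[seg_cols] - base[seg_cols]) / base[seg_cols]
        block = perf[[c for c in ("subject_id", "condition", "kind")
                      if c in perf.columns]].copy()
        block[seg_cols] = pct
        out_rows.append(block)
    return pd.concat(out_rows, ignore_index=True)


def screen_outliers(table: pd.DataFrame, z_threshold: float = 4.0) -> pd.DataFrame:
    """Flag extreme values per parameter using robust (median/MAD) z-scores.

    Report-only: the input is never mutated and nothing is removed. A
    parameter with zero spread produces no flags. Returns a table of
    (row index, subject_id, condition, parameter, value, robust_z) for
    every |z| above the threshold; an empty frame means a clean cohort.
    """
    if table.empty:
        raise SchemaError("cannot screen an empty table")
    flags = []
    for col in _segment_columns(table):
        x = table[col].to_numpy(dtype=float)
        med = np.nanmedian(x)
        mad = median_abs_deviation(x, scale="normal", nan_policy="omit")
        if not np.isfinite(mad) or mad == 0:
            continue
        z = (x - med) / mad
        for i in np.flatnonzero(np.abs(z) > z_threshold):
            flags.append({
                "row": int(table.index[i]),
                "subject_id": table["subject_id"].iloc[i],
                "condition": table["condition"].iloc[i],
                "parameter": col,
                "value": float(x[i]),
                "robust_z": float(z[i]),
            })
    return pd.DataFrame(
        flags, columns=["row", "subject_id", "condition", "parameter",
                        "value", "robust_z"])
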