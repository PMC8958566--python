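"""Face-voice correlations and the performed-self vs control-self contrast.

Pairs each trial's facial percent-change scores with the vocal
parameters measured on the same trial (pitch in cents, loudness in dB,
plus any further prosodic parameters) and reports two-tailed Pearson
correlations with Fisher-z confidence intervals and a Bonferroni flag
across the segment family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import design as design_mod
from .errors import FacekinError, SchemaError

__all__ = ["CorrelationResult", "correlate_face_voice", "compare_self"]

DEFAULT_SEGMENTS = ("brow", "eyebrow", "lips", "jaw")


@dataclass
class CorrelationResult:
    segment: str
    regressor: str
    condition_set: str
    r: float
    r2: float
    p: float
    ci_low: float
    ci_high: float
    df: int
    t: float
    sig: bool

    def to_dict(self) -> dict:
        return {
            "segment": self.segment, "regressor": self.regressor,
            "condition_set": self.condition_set, "r": self.r, "R2": self.r2,
            "p": self.p, "sig": self.sig, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "df": self.df, "t": self.t,
        }


def _pearson(x: np.ndarray, y: np.ndarray, alpha_c: float) -> dict:
    n = x.size
    if n < 3:
        raise FacekinError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": np.nan, "p": np.nan, "ci": (np.nan, np.nan),
                "t": np.nan, "df": n - 2, "sig": False}
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(0.95)
    r = float(res.statistic)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / max(1 - r * r, 1e-300))
    return {"r": r, "p": float(res.pvalue), "ci": (float(ci.low), float(ci.high)),
            "t": float(t), "df": n - 2, "sig": res.pvalue < alpha_c}


def correlate_face_voice(
    face: pd.DataFrame,
    vocal_wide: pd.DataFrame,
    condition_set: str = "character",
    scheme: dict | None = None,
    segments: tuple[str, ...] = DEFAULT_SEGMENTS,
    regressors: tuple[str, ...] = ("pitch", "loudness"),
    alpha: float = 0.05,
    n_tests: int = 4,
) -> list[CorrelationResult]:
    """Pearson correlations between segment scores and vocal parameters.

    ``face`` is the normalized percent-change table; ``vocal_wide`` has
    one row per (subject_id, condition) with one column per vocal
    parameter. The condition set selects which trials enter: all nine
    characters, or the eight emotions excluding neutral. Trials with a
    missing vocal value are dropped pairwise, never imputed.
    """
    for col in ("subject_id", "condition"):
        if col not in face.columns or col not in vocal_wide.columns:
            raise SchemaError(f"both tables need a {col!r} column")
    merged = face.merge(vocal_wide, on=["subject_id", "condition"],
                        suffixes=("", "_vocal"))
    kinds = merged["condition"].map(
        lambda c: design_mod.condition_kind(c, scheme))
    merged = merged[kinds == condition_set]
    alpha_c = alpha / n_tests
    results = []
    for seg in segments:
        for reg in regressors:
            if seg not in merged.columns or reg not in merged.columns:
                raise SchemaError(f"missing column {seg!r} or {reg!r}")
            sub = merged[[seg, reg]].dropna()
            stats_d = _pearson(sub[seg].to_numpy(float),
                               sub[reg].to_numpy(float), alpha_c)
            results.append(CorrelationResult(
                segment=seg, regressor=reg, condition_set=condition_set,
                r=stats_d["r"], r2=stats_d["r"] ** 2, p=stats_d["p"],
                ci_low=stats_d["ci"][0], ci_high=stats_d["ci"][1],
                df=stats_d["df"], t=stats_d["t"], sig=bool(stats_d["sig"]),
            ))
    return results


def correlations_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def compare_self(performed: pd.DataFrame, control: pd.DataFrame,
                 segments: tuple[str, ...] = DEFAULT_SEGMENTS) -> pd.DataFrame:
    """Paired contrast of performed-self vs control-self per segment.

    Both inputs carry one row per subject with segment percent-change
    columns. Returns per-segment mean difference (performed - control),
    paired t, df, two-tailed p and Cohen's d_z. Positive differences
    mean the performed self was more expanded than the conversational
    control.
    """
    a = performed.set_index("subject_id")
    b = control.set_index("subject_id")
    unpaired = sorted(set(a.index).symmetric_difference(b.index))
    if unpaired:
        raise FacekinError(f"unpaired subjects: {unpaired}")
    b = b.loc[a.index]
    rows = []
    for seg in segments:
        d = a[seg].to_numpy(float) - b[seg].to_numpy(float)
        n = d.size
        sd = d.std(ddof=1)
        if sd == 0:
            t, p = (np.nan, 1.0) if np.allclose(d, 0) else (np.inf, 0.0)
            dz = 0.0 if np.allclose(d, 0) else np.inf
        else:
            t, p = stats.ttest_rel(a[seg], b[seg])
            dz = float(d.mean() / sd)
        rows.append({"segment": seg, "mean_diff": float(d.mean()),
                     "t": float(t), "df": n - 1, "p": float(p),
                     "cohens_dz": dz})
    return pd.DataFrame(rows)
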