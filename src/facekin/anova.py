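"""Per-segment mixed-effects repeated-measures ANOVA.

Each facial segment's percent-change score is analysed with a linear
mixed model: two crossed within-subject factors as fixed effects
(cooperativeness x assertiveness for characters, valence x arousal for
emotions), a random intercept per subject, type III F tests with
Satterthwaite denominator df, and Bonferroni correction across the
family of segments. Effect sizes are the marginal and conditional R^2
of the mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design as design_mod
from .errors import DegenerateModelError, SchemaError
from .lmm import RandomInterceptLMM, fit_random_intercept, satterthwaite_F

__all__ = [
    "AnovaTable",
    "CHARACTER_FACTORS",
    "EMOTION_FACTORS",
    "bonferroni_threshold",
    "fit_segment_model",
    "run_univariate_suite",
]

CHARACTER_FACTORS = ("cooperativeness", "assertiveness")
EMOTION_FACTORS = ("valence", "arousal")

_FACTOR_LEVELS = {
    "cooperativeness": design_mod.LEVELS3,
    "assertiveness": design_mod.LEVELS3,
    "valence": ("positive", "negative"),
    "arousal": ("high", "low"),
}


@dataclass
class AnovaTable:
    """Type III mixed-model ANOVA summary for one response.

    ``effects`` has one row per effect (A, B, A x B) with columns
    SumSq, MeanSq, NumDF, DenDF, F, p, sig; ``emmeans`` holds the
    estimated marginal mean of the response at each factor level.
    """

    response: str
    factors: tuple[str, str]
    effects: pd.DataFrame
    r2_marg: float
    r2_cond: float
    alpha_corrected: float
    n_obs: int
    emmeans: pd.DataFrame = field(default_factory=pd.DataFrame)
    model: RandomInterceptLMM | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.effects.copy()
        out.insert(0, "response", self.response)
        out["R2_marg"] = self.r2_marg
        out["R2_cond"] = self.r2_cond
        return out


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise corrected per-test threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def _design_matrix(table: pd.DataFrame, factors: tuple[str, str]
                   ) -> tuple[np.ndarray, dict[str, np.ndarray], list[str]]:
    """Sum-to-zero coded design matrix with intercept, two main effects
    and their interaction; returns (X, term -> column indices, names)."""
    fa, fb = factors
    Ca = design_mod.sum_contrasts(_FACTOR_LEVELS[fa])
    Cb = design_mod.sum_contrasts(_FACTOR_LEVELS[fb])
    for f in factors:
        bad = set(table[f].dropna()) - set(_FACTOR_LEVELS[f])
        if bad or table[f].isna().any():
            raise SchemaError(f"factor {f!r} has missing or unknown levels {bad}")
    Xa = np.column_stack([table[fa].map(Ca[c]).to_numpy(float) for c in Ca])
    Xb = np.column_stack([table[fb].map(Cb[c]).to_numpy(float) for c in Cb])
    Xab = np.column_stack([Xa[:, i] * Xb[:, j]
                           for i in range(Xa.shape[1])
                           for j in range(Xb.shape[1])])
    X = np.column_stack([np.ones(len(table)), Xa, Xb, Xab])
    pa, pb = Xa.shape[1], Xb.shape[1]
    slices = {
        fa: np.arange(1, 1 + pa),
        fb: np.arange(1 + pa, 1 + pa + pb),
        f"{fa}:{fb}": np.arange(1 + pa + pb, 1 + pa + pb + pa * pb),
    }
    return X, slices, [fa, fb, f"{fa}:{fb}"]


def _emmeans(fit: RandomInterceptLMM, slices: dict[str, np.ndarray],
             factors: tuple[str, str]) -> pd.DataFrame:
    """Marginal means per factor level, averaging the other factor's
    levels with equal weight (so sum-coded terms drop out)."""
    rows = []
    p = fit.beta.shape[0]
    for f in factors:
        levels = _FACTOR_LEVELS[f]
        C = design_mod.sum_contrasts(levels)
        for level in levels:
            x = np.zeros(p)
            x[0] = 1.0
            x[slices[f]] = C.loc[level].to_numpy()
            est = float(x @ fit.beta)
            se = float(np.sqrt(x @ fit.cov_beta @ x))
            rows.append({"factor": f, "level": level, "emmean": est, "se": se})
    return pd.DataFrame(rows)


def fit_segment_model(table: pd.DataFrame, response: str,
                      factors: tuple[str, str] = CHARACTER_FACTORS,
                      group: str = "subject_id", reml: bool = False,
                      alpha: float = 0.05, n_tests: int = 4) -> AnovaTable:
    """Fit the mixed model for one segment and build its ANOVA table.

    The effect rows are ordered main effect A, main effect B, A x B.
    SumSq/MeanSq are on the residual-variance scale (MeanSq = F *
    sigma^2), the convention used by mixed-model type III tables.
    """
    table = table.dropna(subset=[response])
    if table[group].nunique() < 2:
        raise DegenerateModelError("need at least 2 subjects")
    X, slices, terms = _design_matrix(table, factors)
    y = table[response].to_numpy(dtype=float)
    fit = fit_random_intercept(X, y, table[group].to_numpy(), reml=reml)
    alpha_c = bonferroni_threshold(alpha, n_tests)
    rows = []
    for term in terms:
        idx = slices[term]
        L = np.zeros((idx.size, X.shape[1]))
        L[np.arange(idx.size), idx] = 1.0
        F, num_df, den_df, p_val = satterthwaite_F(fit, L)
        rows.append({
            "effect": term.replace(":", " x "),
            "SumSq": F * num_df * fit.sigma2,
            "MeanSq": F * fit.sigma2,
            "NumDF": num_df,
            "DenDF": den_df,
            "F": F,
            "p": p_val,
            "sig": p_val < alpha_c,
        })
    r2m, r2c = fit.r_squared()
    return AnovaTable(
        response=response, factors=factors, effects=pd.DataFrame(rows),
        r2_marg=r2m, r2_cond=r2c, alpha_corrected=alpha_c, n_obs=len(table),
        emmeans=_emmeans(fit, slices, factors), model=fit,
    )


def run_univariate_suite(normalized: pd.DataFrame, kind: str = "character",
                         segments: tuple[str, ...] = ("brow", "eyebrow",
                                                      "lips", "jaw"),
                         scheme: dict | None = None, reml: bool = False,
                         alpha: float = 0.05) -> dict[str, AnovaTable | Exception]:
    """One mixed-model ANOVA per segment for the character or emotion design.

    ``normalized`` is the percent-change table (one row per subject x
    condition). Rows of other kinds (the baseline was already excluded
    at normalization; control-self is excluded here) are dropped. A
    failing segment records its exception and the suite continues.
    """
    if kind == "character":
        factors = CHARACTER_FACTORS
    elif kind == "emotion":
        factors = EMOTION_FACTORS
    else:
        raise ValueError(f"kind must be character|emotion, got {kind!r}")
    dtable = design_mod.build_design_table(normalized, scheme)
    dtable = dtable[dtable["kind"] == kind]
    out: dict[str, AnovaTable | Exception] = {}
    for seg in segments:
        if seg not in dtable.columns:
            out[seg] = SchemaError(f"segment column {seg!r} missing")
            continue
        try:
            out[seg] = fit_segment_model(
                dtable, seg, factors=factors, reml=reml, alpha=alpha,
                n_tests=len(segments),
            )
        except Exception as exc:  # propagate per-segment, keep going
            out[seg] = exc
    return out


def suite_frame(suite: dict[str, AnovaTable | Exception]) -> pd.DataFrame:
    """Concatenate a suite's per-segment tables (errors skipped)."""
    frames = [t.to_frame() for t in suite.values() if isinstance(t, AnovaTable)]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
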