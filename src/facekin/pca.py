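"""Multimodal varimax-rotated PCA over facial and vocal parameters.

Combines the four facial segment scores with the vocal parameter set
(16 parameters in the default configuration) across all character and
emotion trials, z-scores each parameter within subject, imputes isolated
missing trials by the same-condition cross-subject mean, and extracts
principal components on the correlation scale. The retained components
(default two) are rotated with the varimax criterion so that each
rotated component concentrates on an interpretable block of parameters;
per-condition mean component scores place every character and emotion
in the rotated space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FacekinError

__all__ = [
    "PcaResult",
    "zscore_within_subject",
    "impute_similar_case",
    "select_n_components",
    "varimax",
    "pca_varimax",
    "classify_loading",
]

ID_COLUMNS = ("subject_id", "condition", "kind")


def _param_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


def zscore_within_subject(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score every parameter within subject across that subject's
    conditions (sample SD, ddof=1).

    Puts parameters with different native scales (percent, cents, dB,
    seconds) on a common footing and absorbs between-subject level
    differences. Missing cells stay missing. A subject with fewer than
    two non-missing conditions for a parameter, or with zero variance
    there, is an error naming subject and parameter.
    """
    params = _param_columns(table)
    out = table.copy()
    for subject, grp in table.groupby("subject_id", sort=False):
        if len(grp) < 2:
            raise FacekinError(
                f"subject {subject!r} has fewer than 2 conditions")
        for col in params:
            x = grp[col].astype(float)
            n = x.notna().sum()
            if n >= 2:
                sd = x.std(ddof=1)
                if not sd > 0:
                    raise FacekinError(
                        f"zero within-subject variance: subject {subject!r}, "
                        f"parameter {col!r}")
                out.loc[grp.index, col] = (x - x.mean()) / sd
            elif n == 1:
                raise FacekinError(
                    f"subject {subject!r}, parameter {col!r}: a single "
                    "observation cannot be z-scored")
    return out


def impute_similar_case(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Similar-case mean imputation of missing cells (done after z-scoring).

    Each missing (subject, condition, parameter) cell is replaced by the
    mean of that parameter over the *same condition* across the other
    subjects — the most similar observed cases. Returns the completed
    table and a flag table of imputed cells; no donors is an error.
    """
    params = _param_columns(table)
    out = table.copy()
    flags = []
    for col in params:
        missing = out.index[out[col].isna()]
        for idx in missing:
            cond = out.at[idx, "condition"]
            donors = out[(out["condition"] == cond) & (out.index != idx)][col]
            donors = donors.dropna()
            if donors.empty:
                raise FacekinError(
                    f"no donors to impute parameter {col!r} for condition "
                    f"{cond!r}")
            out.at[idx, col] = donors.mean()
            flags.append({"subject_id": out.at[idx, "subject_id"],
                          "condition": cond, "parameter": col,
                          "imputed_value": float(donors.mean())})
    return out, pd.DataFrame(flags, columns=["subject_id", "condition",
                                             "parameter", "imputed_value"])


def select_n_components(eigenvalues: np.ndarray) -> tuple[int, pd.DataFrame]:
    """Kaiser count (eigenvalues strictly > 1) plus scree-plot data.

    The scree table carries each component's eigenvalue and the drop to
    the next one, the data a scree elbow is read from. The pipeline's
    retained k is a configuration choice (default 2); this reports the
    retention heuristics.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue sequence")
    if np.any(np.diff(ev) > 1e-10):
        raise ValueError("eigenvalues must be in descending order")
    kaiser = int(np.sum(ev > 1.0))
    scree = pd.DataFrame({
        "component": np.arange(1, ev.size + 1),
        "eigenvalue": ev,
        "drop_to_next": np.append(-np.diff(ev), np.nan),
    })
    return kaiser, scree


def varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax objective: summed variance of squared loadings."""
    sq = L ** 2
    return float(np.sum(sq ** 2) - np.sum(sq.sum(axis=0) ** 2) / L.shape[0])


def varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-12,
            max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Kaiser row normalization (default) divides each row by its
    communality before rotating, the convention of the classical
    algorithm. Returns ``(rotated_loadings, R)`` with ``rotated =
    loadings @ R`` and R orthogonal.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k == 1:
        return L.copy(), np.eye(1)
    h = np.sqrt((L ** 2).sum(axis=1)) if normalize else np.ones(p)
    h[h == 0] = 1.0
    A = L / h[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Ar = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (Ar ** 3 - Ar @ np.diag((Ar ** 2).sum(axis=0)) / p))
        R = u @ vt
        d_new = s.sum()
        if d_new <= d * (1 + tol):
            break
        d = d_new
    return (A @ R) * h[:, None], R


@dataclass
class PcaResult:
    """Rotated principal-component summary of the multimodal table."""

    parameters: list[str]
    eigenvalues: np.ndarray
    k: int
    loadings_unrotated: np.ndarray  # (p, k)
    loadings_rotated: np.ndarray    # (p, k)
    rotation: np.ndarray            # (k, k) orthogonal
    variance_fraction: np.ndarray   # per rotated component, of total variance
    scores: pd.DataFrame            # per (subject, condition) rotated scores
    condition_scores: pd.DataFrame  # per-condition means across subjects
    kaiser_k: int
    scree: pd.DataFrame

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings_rotated ** 2).sum(axis=1)

    def loadings_frame(self) -> pd.DataFrame:
        cols = {f"RC{i + 1}": self.loadings_rotated[:, i] for i in range(self.k)}
        df = pd.DataFrame({"parameter": self.parameters, **cols})
        for i in range(self.k):
            df[f"RC{i + 1}_band"] = [classify_loading(v)
                                     for v in self.loadings_rotated[:, i]]
        return df


def pca_varimax(table: pd.DataFrame, k: int = 2) -> PcaResult:
    """Correlation-scale PCA with varimax rotation of the first k components.

    ``table`` must be complete (z-scored and imputed), one row per
    (subject, condition), one column per parameter. Each rotated
    component is sign-flipped so its largest-magnitude loading is
    positive, making outputs reproducible despite the sign indeterminacy
    of the decomposition.
    """
    params = _param_columns(table)
    p = len(params)
    if not 1 <= k <= p:
        raise ConfigurationError(f"k={k} outside 1..{p}")
    Xraw = table[params].to_numpy(dtype=float)
    if np.isnan(Xraw).any():
        raise FacekinError("table has missing values; impute first")
    mu = Xraw.mean(axis=0)
    sd = Xraw.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [params[i] for i in np.flatnonzero(sd == 0)]
        raise FacekinError(f"zero-variance parameters: {bad}")
    Z = (Xraw - mu) / sd
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    kaiser_k, scree = select_n_components(evals)

    load_unrot = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    load_rot, R = varimax(load_unrot)

    # fix sign: the largest-|loading| parameter of each component loads +
    flip = np.ones(k)
    for j in range(k):
        m = int(np.argmax(np.abs(load_rot[:, j])))
        if load_rot[m, j] < 0:
            flip[j] = -1.0
    load_rot = load_rot * flip
    R = R * flip

    # standardized component scores, rotated with the same orthogonal map
    with np.errstate(divide="ignore"):
        scores_unrot = Z @ evecs[:, :k] / np.sqrt(np.maximum(evals[:k], 1e-300))
    scores_rot = scores_unrot @ R
    score_cols = {f"RC{i + 1}": scores_rot[:, i] for i in range(k)}
    scores = pd.DataFrame({
        "subject_id": table["subject_id"].to_numpy(),
        "condition": table["condition"].to_numpy(),
        **score_cols,
    })
    condition_scores = (scores.drop(columns="subject_id")
                        .groupby("condition", sort=False).mean().reset_index())

    var_frac = (load_rot ** 2).sum(axis=0) / p
    return PcaResult(
        parameters=params, eigenvalues=evals, k=k,
        loadings_unrotated=load_unrot, loadings_rotated=load_rot,
        rotation=R, variance_fraction=var_frac, scores=scores,
        condition_scores=condition_scores, kaiser_k=kaiser_k, scree=scree,
    )


#: Loading-magnitude interpretation bands.
_BANDS = (
    (0.35, "below"),
    (0.50, "moderately_low"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (np.inf, "very_strong"),
)


def classify_loading(value: float) -> str:
    """Interpretation band for a loading magnitude.

    below (<0.35), moderately_low (0.35-0.49), moderate (0.50-0.59),
    strong (0.60-0.79), very_strong (>=0.80); sign is ignored.
    """
    a = abs(float(value))
    if a > 1 + 1e-12:
        raise ValueError(f"|loading| > 1: {value}")
    for bound, label in _BANDS:
        if a < bound:
            return label
    raise AssertionError("unreachable")
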