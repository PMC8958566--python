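"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: the ANOVA oracle
is the textbook balanced two-way within-subject decomposition with the
subject as an additive block, and the varimax oracle is a brute-force
scan over the single rotation angle available to a two-component
solution.
"""

import numpy as np
import pandas as pd
from scipy import stats


def rm_anova_pooled(df: pd.DataFrame, response: str, factor_a: str,
                    factor_b: str, subject: str) -> pd.DataFrame:
    """Closed-form balanced repeated-measures ANOVA with pooled error.

    Model: y = mu + subject + A + B + A:B + error, all cells observed
    once per subject. This is the classical compound-symmetry analysis a
    random-intercept mixed model reproduces on balanced data.
    """
    y = df[response].to_numpy(float)
    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)

    def ss_of(group_cols):
        g = df.groupby(group_cols, observed=True)[response]
        return float((g.size() * (g.mean() - grand) ** 2).sum())

    ss_a = ss_of([factor_a])
    ss_b = ss_of([factor_b])
    ss_subj = ss_of([subject])
    ss_cells = ss_of([factor_a, factor_b])
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ss_total - ss_subj - ss_cells

    a = df[factor_a].nunique()
    b = df[factor_b].nunique()
    s = df[subject].nunique()
    n = len(df)
    df_err = n - s - (a * b - 1)
    rows = []
    for name, ss, df_num in (
        (factor_a, ss_a, a - 1),
        (factor_b, ss_b, b - 1),
        (f"{factor_a} x {factor_b}", ss_ab, (a - 1) * (b - 1)),
    ):
        ms = ss / df_num
        F = ms / (ss_err / df_err)
        rows.append({"effect": name, "SS": ss, "df1": df_num, "df2": df_err,
                     "F": F, "p": float(stats.f.sf(F, df_num, df_err))})
    return pd.DataFrame(rows)


def varimax_criterion_normalized(L: np.ndarray) -> float:
    """Varimax objective on Kaiser-normalized loadings."""
    h = np.sqrt((L ** 2).sum(axis=1))
    h[h == 0] = 1.0
    A = L / h[:, None]
    sq = A ** 2
    return float(np.sum(sq ** 2) - np.sum(sq.sum(axis=0) ** 2) / L.shape[0])


def best_rotation_angle(loadings: np.ndarray, step: float = 0.001) -> float:
    """Brute-force scan of the planar rotation angle maximizing the
    varimax criterion for a two-column loading matrix.

    The criterion has period pi/2 in the angle (column swap + sign), so
    only [0, pi/2) is scanned.
    """
    assert loadings.shape[1] == 2
    angles = np.arange(0.0, np.pi / 2, step)
    best, best_v = 0.0, -np.inf
    for t in angles:
        R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        v = varimax_criterion_normalized(loadings @ R)
        if v > best_v:
            best, best_v = t, v
    return best


def rotation_angle_mod(R: np.ndarray) -> float:
    """Canonical planar angle in [0, pi/2) of a 2x2 orthogonal matrix,
    modulo the column swaps and sign flips varimax cannot distinguish."""
    t = float(np.arctan2(R[1, 0], R[0, 0]))
    return t % (np.pi / 2)
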