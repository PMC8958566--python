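"""The mixed model: agreement with independent implementations
(statsmodels, lme4/lmerTest), classical-ANOVA equivalence, Satterthwaite
df bookkeeping, R^2 properties, and degenerate inputs."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from facekin.anova import bonferroni_threshold, fit_segment_model
from facekin.config import SimConfig
from facekin.design import build_design_table
from facekin.errors import DegenerateModelError
from facekin.lmm import fit_random_intercept, satterthwaite_F
from facekin.simulate import simulate_normalized_table
from oracle_helpers import rm_anova_pooled


def character_table(seed=3, n_subjects=12, **overrides):
    cfg = SimConfig(seed=seed, n_subjects=n_subjects, **overrides)
    t = simulate_normalized_table(cfg)
    d = build_design_table(t)
    return d[d["kind"] == "character"].reset_index(drop=True)


@pytest.fixture(scope="module")
def char12():
    return character_table()


def test_ml_fit_matches_statsmodels(char12):
    import statsmodels.formula.api as smf

    fit = fit_segment_model(char12, "brow", reml=False)
    m = smf.mixedlm(
        "brow ~ C(cooperativeness, Sum) * C(assertiveness, Sum)",
        char12, groups=char12["subject_id"]).fit(reml=False)
    assert fit.model.sigma2 == pytest.approx(float(m.scale), rel=1e-4)
    assert fit.model.tau2 == pytest.approx(
        float(m.cov_re.iloc[0, 0]), rel=1e-3)
    assert fit.model.loglik == pytest.approx(float(m.llf), abs=1e-4)


def test_matches_lmertest_reference(char12, tmp_path):
    """Full type III Satterthwaite table agreement with lmerTest."""
    fixture = tmp_path / "d.csv"
    char12[["subject_id", "cooperativeness", "assertiveness", "brow"]
           ].to_csv(fixture, index=False)
    rscript = tmp_path / "check.R"
    rscript.write_text(
        'suppressMessages(library(lmerTest))\n'
        f'd <- read.csv("{fixture}")\n'
        'd$cooperativeness <- factor(d$cooperativeness,'
        ' levels=c("low","medium","high"))\n'
        'd$assertiveness <- factor(d$assertiveness,'
        ' levels=c("low","medium","high"))\n'
        'contrasts(d$cooperativeness) <- contr.sum(3)\n'
        'contrasts(d$assertiveness) <- contr.sum(3)\n'
        'for (reml in c(FALSE, TRUE)) {\n'
        '  m <- lmer(brow ~ cooperativeness*assertiveness + (1|subject_id),'
        ' data=d, REML=reml)\n'
        '  a <- anova(m, type=3)\n'
        '  write.csv(data.frame(F=a$"F value", DenDF=a$DenDF,'
        ' p=a$"Pr(>F)"),\n'
        f'    file.path("{tmp_path}", paste0("ref_", reml, ".csv")),'
        ' row.names=FALSE)\n'
        '}\n')
    subprocess.run(["Rscript", str(rscript)], check=True,
                   capture_output=True, text=True)
    for reml, tag in ((False, "FALSE"), (True, "TRUE")):
        ref = pd.read_csv(tmp_path / f"ref_{tag}.csv")
        ours = fit_segment_model(char12, "brow", reml=reml).effects
        np.testing.assert_allclose(ours["F"], ref["F"], rtol=1e-4)
        np.testing.assert_allclose(ours["DenDF"], ref["DenDF"], rtol=1e-2)
        np.testing.assert_allclose(ours["p"], ref["p"], rtol=1e-3,
                                   atol=1e-12)


def test_reml_equals_classical_rm_anova(char12):
    oracle = rm_anova_pooled(char12, "brow", "cooperativeness",
                             "assertiveness", "subject_id")
    ours = fit_segment_model(char12, "brow", reml=True).effects
    np.testing.assert_allclose(ours["F"], oracle["F"], rtol=1e-6)
    np.testing.assert_allclose(ours["DenDF"], oracle["df2"], rtol=1e-4)


def test_ml_denominator_df_is_n_minus_subjects(char12):
    """On a balanced design the ML Satterthwaite denominator df equals
    n_obs - n_subjects (the profile-likelihood residual dimension)."""
    tab = fit_segment_model(char12, "brow", reml=False)
    expected = tab.n_obs - char12["subject_id"].nunique()
    np.testing.assert_allclose(tab.effects["DenDF"], expected, rtol=1e-3)


def test_numerator_dfs(char12):
    tab = fit_segment_model(char12, "brow")
    assert tab.effects["NumDF"].tolist() == [2.0, 2.0, 4.0]
    assert (tab.effects["SumSq"] >= 0).all()
    assert tab.effects["MeanSq"].equals(tab.effects["SumSq"] /
                                        tab.effects["NumDF"])


def test_emotion_design_fits_with_correct_dfs():
    cfg = SimConfig(seed=9, n_subjects=12)
    t = simulate_normalized_table(cfg)
    d = build_design_table(t)
    emo = d[d["kind"] == "emotion"]
    assert len(emo) == 12 * 8
    tab = fit_segment_model(emo, "jaw", factors=("valence", "arousal"))
    assert tab.effects["NumDF"].tolist() == [1.0, 1.0, 1.0]
    assert tab.effects.iloc[1]["p"] < 0.05  # injected arousal effect on jaw


def test_r_squared_properties(char12):
    tab = fit_segment_model(char12, "brow")
    assert 0 <= tab.r2_marg <= tab.r2_cond <= 1
    # no subject variance: marginal ~ conditional
    flat = character_table(seed=21, subject_sd=0.0)
    t2 = fit_segment_model(flat, "brow")
    assert t2.r2_cond - t2.r2_marg == pytest.approx(0.0, abs=0.02)
    # null effects, null couplings: marginal ~ 0
    null = character_table(
        seed=22, n_subjects=24,
        cooperativeness_effects={}, assertiveness_effects={},
        valence_effects={}, arousal_effects={})
    t3 = fit_segment_model(null, "brow")
    assert t3.r2_marg == pytest.approx(0.0, abs=0.05)


def test_permuting_conditions_within_subject_destroys_significance(char12):
    rng = np.random.default_rng(0)
    pvals = []
    for _ in range(10):
        shuffled = char12.copy()
        for _, idx in shuffled.groupby("subject_id").groups.items():
            cols = ["cooperativeness", "assertiveness",
                    "cooperativeness_c1", "cooperativeness_c2",
                    "assertiveness_c1", "assertiveness_c2"]
            perm = rng.permutation(len(idx))
            shuffled.loc[idx, cols] = shuffled.loc[idx, cols].to_numpy()[perm]
        tab = fit_segment_model(shuffled, "brow")
        pvals.append(tab.effects.iloc[0]["p"])  # cooperativeness
    assert np.median(pvals) > 0.2


def test_degenerate_inputs_rejected(char12):
    flat = char12.copy()
    flat["brow"] = 1.0
    with pytest.raises(DegenerateModelError, match="zero variance"):
        fit_segment_model(flat, "brow")
    X = np.column_stack([np.ones(20), np.arange(20.0), np.arange(20.0)])
    y = np.arange(20.0) + np.random.default_rng(0).normal(size=20)
    with pytest.raises(DegenerateModelError, match="rank deficient"):
        fit_random_intercept(X, y, np.repeat(np.arange(4), 5))
    with pytest.raises(DegenerateModelError, match="2 groups"):
        fit_random_intercept(X[:, :2], y, np.zeros(20, dtype=int))


def test_bonferroni_threshold_values():
    assert bonferroni_threshold(0.05, 4) == pytest.approx(0.0125)
    assert bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)
    with pytest.raises(ValueError):
        bonferroni_threshold(1.5, 4)


def test_single_df_contrast_matches_t_test_shape(char12):
    fit = fit_segment_model(char12, "brow").model
    L = np.zeros((1, fit.beta.size))
    L[0, 1] = 1.0
    F, q, den, p = satterthwaite_F(fit, L)
    assert q == 1.0
    assert 0 <= p <= 1
    assert den > 2
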