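"""Within-subject z-scoring, similar-case imputation, component
selection, varimax rotation, and loading interpretation bands."""

import numpy as np
import pandas as pd
import pytest

from facekin.config import SimConfig
from facekin.errors import FacekinError
from facekin.mocap import vocal_wide
from facekin.pca import (classify_loading, impute_similar_case, pca_varimax,
                         select_n_components, varimax, zscore_within_subject)
from facekin.simulate import (draw_condition_targets,
                              simulate_normalized_table, simulate_vocal_table)
from oracle_helpers import (best_rotation_angle, rotation_angle_mod,
                            varimax_criterion_normalized)


def multiparam_table(n_subjects=8, n_conditions=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for j in range(n_conditions):
            rows.append({"subject_id": f"S{i}", "condition": f"c{j}",
                         "p1": rng.normal(10, 2), "p2": rng.normal(-5, 9)})
    return pd.DataFrame(rows)


def multimodal_table(seed=1, **overrides):
    cfg = SimConfig(seed=seed, **overrides)
    targets = draw_condition_targets(cfg)
    face = targets[targets["condition"] != "control_self"]
    vocal = vocal_wide(simulate_vocal_table(targets, cfg))
    return cfg, face.merge(vocal, on=["subject_id", "condition"], how="left")


def test_zscore_within_subject_definition():
    t = multiparam_table()
    z = zscore_within_subject(t)
    for _, grp in z.groupby("subject_id"):
        assert grp["p1"].mean() == pytest.approx(0.0, abs=1e-12)
        assert grp["p1"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_zscore_location_invariance():
    t = multiparam_table()
    shifted = t.copy()
    shifted.loc[shifted["subject_id"] == "S0", "p1"] += 500.0
    pd.testing.assert_frame_equal(zscore_within_subject(t),
                                  zscore_within_subject(shifted))


def test_zscore_degenerate_subjects_rejected():
    t = multiparam_table(n_conditions=1)
    with pytest.raises(FacekinError, match="fewer than 2"):
        zscore_within_subject(t)
    t2 = multiparam_table()
    t2.loc[t2["subject_id"] == "S0", "p1"] = 3.0
    with pytest.raises(FacekinError, match="zero within-subject variance"):
        zscore_within_subject(t2)


def test_impute_similar_case_mean_of_condition_donors():
    t = multiparam_table(n_subjects=4)
    t.loc[(t["subject_id"] == "S0") & (t["condition"] == "c1"), "p1"] = np.nan
    donors = t[(t["condition"] == "c1") & (t["subject_id"] != "S0")]["p1"]
    filled, flags = impute_similar_case(t)
    got = filled[(filled["subject_id"] == "S0")
                 & (filled["condition"] == "c1")]["p1"].iloc[0]
    assert got == pytest.approx(donors.mean())
    assert len(flags) == 1
    assert flags.iloc[0]["parameter"] == "p1"
    assert not filled[["p1", "p2"]].isna().any().any()


def test_impute_constant_donors_and_no_donors():
    t = multiparam_table(n_subjects=3)
    t["p1"] = 0.7
    t.loc[0, "p1"] = np.nan
    filled, _ = impute_similar_case(t)
    assert filled.loc[0, "p1"] == pytest.approx(0.7)
    t2 = multiparam_table(n_subjects=2)
    t2.loc[t2["condition"] == "c0", "p1"] = np.nan
    with pytest.raises(FacekinError, match="no donors"):
        impute_similar_case(t2)


def test_kaiser_counts_and_scree():
    k, scree = select_n_components(np.array([3.2, 1.4, 0.9, 0.5]))
    assert k == 2
    assert scree["drop_to_next"].iloc[0] == pytest.approx(1.8)
    k_id, _ = select_n_components(np.ones(5))
    assert k_id == 0  # strict inequality
    with pytest.raises(ValueError):
        select_n_components(np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        select_n_components(np.array([]))


def test_varimax_k1_is_identity_up_to_sign():
    L = np.array([[0.9], [0.5], [-0.3]])
    rotated, R = varimax(L)
    assert abs(float(R[0, 0])) == pytest.approx(1.0)
    np.testing.assert_allclose(np.abs(rotated), np.abs(L))


def test_varimax_preserves_communalities_and_improves_criterion():
    rng = np.random.default_rng(5)
    L = rng.normal(size=(16, 2)) * [1.0, 0.6]
    rotated, R = varimax(L)
    np.testing.assert_allclose(R @ R.T, np.eye(2), atol=1e-12)
    np.testing.assert_allclose((rotated ** 2).sum(axis=1),
                               (L ** 2).sum(axis=1), atol=1e-9)
    # the rotation maximizes the Kaiser-normalized criterion
    assert varimax_criterion_normalized(rotated) >= \
        varimax_criterion_normalized(L) - 1e-12


def test_varimax_matches_bruteforce_angle():
    rng = np.random.default_rng(8)
    # two-block structure plus noise, like the multimodal table
    L = np.zeros((16, 2))
    L[:8, 0] = rng.uniform(0.5, 0.9, 8)
    L[8:, 1] = rng.uniform(0.4, 0.8, 8)
    L += rng.normal(0, 0.1, size=L.shape)
    start = np.array([[np.cos(0.7), -np.sin(0.7)], [np.sin(0.7), np.cos(0.7)]])
    L_mixed = L @ start
    _, R = varimax(L_mixed)
    oracle = best_rotation_angle(L_mixed)
    got = rotation_angle_mod(R)
    delta = abs(got - oracle)
    assert min(delta, np.pi / 2 - delta) < 0.01


def test_pca_invariants_on_multimodal_table():
    _, table = multimodal_table()
    z = zscore_within_subject(table)
    complete, _ = impute_similar_case(z)
    res = pca_varimax(complete, k=2)
    assert res.eigenvalues.sum() == pytest.approx(16.0, abs=1e-9)
    # communalities preserved by the orthogonal rotation
    np.testing.assert_allclose((res.loadings_rotated ** 2).sum(axis=1),
                               (res.loadings_unrotated ** 2).sum(axis=1),
                               atol=1e-9)
    # total retained variance preserved
    assert (res.loadings_rotated ** 2).sum() == pytest.approx(
        (res.loadings_unrotated ** 2).sum(), abs=1e-9)
    # sign convention: dominant parameter of each component loads +
    for j in range(2):
        m = np.argmax(np.abs(res.loadings_rotated[:, j]))
        assert res.loadings_rotated[m, j] > 0
    assert np.all(res.variance_fraction >= 0)
    assert res.variance_fraction.sum() <= 1 + 1e-12


def test_structure_recovery_blocks_and_condition_ordering():
    """The intensity block (jaw, pitch, loudness) and quality block
    (brow/eyebrow/lips vs duration/timbre) land on separate rotated
    components, and condition means order along the designed factors."""
    cfg, table = multimodal_table(seed=2)
    z = zscore_within_subject(table)
    complete, _ = impute_similar_case(z)
    res = pca_varimax(complete, k=2)
    load = {p: res.loadings_rotated[i] for i, p in enumerate(res.parameters)}
    intensity_axis = int(np.argmax(np.abs(load["jaw"])))
    quality_axis = 1 - intensity_axis
    for p in ("jaw", "pitch", "loudness"):
        assert np.argmax(np.abs(load[p])) == intensity_axis, p
    for p in ("brow", "eyebrow", "lips", "duration", "spectral_tilt"):
        assert np.argmax(np.abs(load[p])) == quality_axis, p
    # duration/timbre oppose the facial quality block in sign
    assert load["duration"][quality_axis] * load["brow"][quality_axis] < 0

    cond = res.condition_scores.set_index("condition")
    ax_i, ax_q = f"RC{intensity_axis + 1}", f"RC{quality_axis + 1}"
    sgn_i = np.sign(load["jaw"][intensity_axis])
    sgn_q = np.sign(load["brow"][quality_axis])
    scheme = cfg.character_scheme
    by_assert = {lvl: np.mean([cond.loc[c, ax_i] for c, (co, a) in
                               scheme.items() if a == lvl])
                 for lvl in ("low", "medium", "high")}
    assert sgn_i * by_assert["low"] < sgn_i * by_assert["high"]
    by_coop = {lvl: np.mean([cond.loc[c, ax_q] for c, (co, a) in
                             scheme.items() if co == lvl])
               for lvl in ("low", "medium", "high")}
    assert sgn_q * by_coop["low"] < sgn_q * by_coop["high"]
    # emotions: positive valence right of negative on the quality axis,
    # high arousal above low on the intensity axis
    pos = np.mean([cond.loc[c, ax_q] for c in ("happy", "proud", "surprised",
                                               "calm")])
    neg = np.mean([cond.loc[c, ax_q] for c in ("angry", "fearful",
                                               "disgusted", "sad")])
    assert sgn_q * pos > sgn_q * neg
    high = np.mean([cond.loc[c, ax_i] for c in ("happy", "proud", "surprised",
                                                "angry", "fearful",
                                                "disgusted")])
    low = np.mean([cond.loc[c, ax_i] for c in ("calm", "sad")])
    assert sgn_i * high > sgn_i * low


@pytest.mark.parametrize("value, band", [
    (0.10, "below"), (0.34, "below"),
    (0.35, "moderately_low"), (-0.45, "moderately_low"),
    (0.55, "moderate"), (0.65, "strong"), (-0.79, "strong"),
    (-0.85, "very_strong"), (0.80, "very_strong"), (1.0, "very_strong"),
])
def test_loading_bands(value, band):
    assert classify_loading(value) == band


def test_loading_band_rejects_impossible_magnitude():
    with pytest.raises(ValueError):
        classify_loading(1.2)
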