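"""The synthetic-cohort generator: determinism, geometric similarity,
analytic ground truth, dropout expectations, and file validity."""

import numpy as np
import pandas as pd
import pytest

from conftest import tiny_sim_config
from facekin.config import SimConfig
from facekin.mocap import read_trial
from facekin.normalize import normalize_cohort
from facekin.segments import (DEFAULT_SEGMENTS, extract_trial_features,
                              features_to_frame)
from facekin.simulate import (condition_list, draw_condition_targets,
                              simulate_cohort, simulate_subject_geometry,
                              simulate_trial)

CLEAN = dict(jitter_sd_mm=0.0, dropout=0.0, face_scale_sd=0.0)


def clean_config(**overrides):
    kw = dict(n_subjects=2, duration_s=2.0, seed=3, **CLEAN)
    kw.update(overrides)
    return SimConfig(**kw)


def segment_means(traj):
    return extract_trial_features(traj).mean_length_mm


def test_geometry_deterministic_and_scaled():
    cfg = SimConfig(seed=5, face_scale_sd=0.1)
    g1 = simulate_subject_geometry(cfg, 3)
    g2 = simulate_subject_geometry(cfg, 3)
    assert g1 == g2
    flat = SimConfig(seed=5, face_scale_sd=0.0)
    scales = {simulate_subject_geometry(flat, i).scale for i in range(5)}
    assert scales == {1.0}


def test_scale_factor_scales_all_neutral_lengths():
    cfg = clean_config(articulation_amplitude_mm={}, head_sway_mm=0.0)
    g = simulate_subject_geometry(cfg, 0)
    base = segment_means(simulate_trial(g, {}, cfg, scale_override=1.0))
    big = segment_means(simulate_trial(g, {}, cfg, scale_override=1.2))
    for seg in base:
        assert big[seg] == pytest.approx(1.2 * base[seg], rel=1e-12)


def test_neutral_percent_change_is_zero_without_noise():
    cfg = clean_config()
    g = simulate_subject_geometry(cfg, 0)
    neutral = segment_means(simulate_trial(g, {}, cfg, trial_index=0))
    again = segment_means(simulate_trial(g, {}, cfg, trial_index=1))
    for seg in neutral:
        pct = 100 * (again[seg] - neutral[seg]) / neutral[seg]
        assert pct == pytest.approx(0.0, abs=1e-9)


def test_injected_brow_offset_recovered_exactly():
    cfg = clean_config()
    g = simulate_subject_geometry(cfg, 0)
    neutral = segment_means(simulate_trial(g, {}, cfg, trial_index=0))
    perf = segment_means(simulate_trial(g, {"brow": 10.0}, cfg, trial_index=1))
    pct = 100 * (perf["brow"] - neutral["brow"]) / neutral["brow"]
    assert pct == pytest.approx(10.0, abs=1e-6)


def test_articulation_cancels_in_percent_change():
    """The articulated segments (lips, jaw) recover their designed
    offsets because the oscillation is identical in the baseline."""
    cfg = clean_config(duration_s=10.0)
    g = simulate_subject_geometry(cfg, 0)
    neutral = segment_means(simulate_trial(g, {}, cfg, trial_index=0))
    perf = segment_means(simulate_trial(g, {"lips": 6.0, "jaw": -4.0}, cfg,
                                        trial_index=1))
    assert 100 * (perf["lips"] / neutral["lips"] - 1) == pytest.approx(
        6.0, abs=1e-6)
    assert 100 * (perf["jaw"] / neutral["jaw"] - 1) == pytest.approx(
        -4.0, abs=1e-6)


def test_doubling_face_scale_leaves_percent_change_unchanged():
    """Full-trajectory scale invariance, with jitter and head sway on."""
    cfg = SimConfig(n_subjects=1, duration_s=2.0, seed=9, jitter_sd_mm=0.4,
                    dropout=0.0)
    g = simulate_subject_geometry(cfg, 0)

    def pct_changes(scale):
        neutral = segment_means(
            simulate_trial(g, {}, cfg, trial_index=0, scale_override=scale))
        perf = segment_means(
            simulate_trial(g, {"brow": 5.0, "jaw": 3.0}, cfg, trial_index=1,
                           scale_override=scale))
        return {s: 100 * (perf[s] - neutral[s]) / neutral[s] for s in perf}

    a, b = pct_changes(1.0), pct_changes(2.0)
    for seg in a:
        assert b[seg] == pytest.approx(a[seg], rel=1e-9)


def test_dropout_coverage_follows_and_rule():
    cfg = SimConfig(n_subjects=1, duration_s=30.0, seed=2, dropout=0.3,
                    jitter_sd_mm=0.0)
    g = simulate_subject_geometry(cfg, 0)
    traj = simulate_trial(g, {}, cfg)
    feats = extract_trial_features(traj, min_coverage=0.0)
    for seg in feats.coverage.values():
        assert seg == pytest.approx(0.49, abs=0.03)


def test_cohort_counts_and_file_validity(tiny_cohort):
    cohort, out = tiny_cohort
    cfg = tiny_sim_config()
    assert len(cohort.manifest) == cfg.n_subjects * 19
    assert set(cohort.manifest["condition"]) == set(condition_list(cfg))
    # the generator never writes an invalid file
    for path in cohort.manifest["path"].head(3):
        traj = read_trial(path)
        assert traj.n_frames == int(cfg.duration_s * cfg.sample_rate)
        assert len(traj.marker_labels) == 7
    # vocal rows: no control_self, all parameters present
    assert not (cohort.vocal["condition"] == "control_self").any()
    assert cohort.vocal.groupby(["subject_id", "condition"]).size().eq(
        12).all()


def test_cohort_bit_reproducible(tmp_path):
    cfg = tiny_sim_config(seed=42, n_subjects=2)
    c1 = simulate_cohort(cfg, tmp_path / "a")
    c2 = simulate_cohort(cfg, tmp_path / "b")
    pd.testing.assert_frame_equal(c1.vocal, c2.vocal)
    pd.testing.assert_frame_equal(c1.targets, c2.targets)
    f1 = sorted((tmp_path / "a" / "trials").iterdir())
    f2 = sorted((tmp_path / "b" / "trials").iterdir())
    assert [p.name for p in f1] == [p.name for p in f2]
    for p1, p2 in zip(f1[:4], f2[:4]):
        assert p1.read_bytes() == p2.read_bytes()


def test_pipeline_recovers_targets_through_trajectories(tiny_cohort):
    """End-to-end: extract + normalize on real trajectory files recovers
    the generator's designed percent targets up to jitter noise."""
    cohort, out = tiny_cohort
    feats = []
    for _, row in cohort.manifest.iterrows():
        traj = read_trial(row["path"])
        feats.append(extract_trial_features(
            traj, DEFAULT_SEGMENTS, subject_id=row["subject_id"],
            condition=row["condition"], min_coverage=0.3))
    normalized = normalize_cohort(features_to_frame(feats))
    merged = normalized.merge(cohort.targets, on=["subject_id", "condition"],
                              suffixes=("", "_target"))
    for seg in ("brow", "eyebrow", "lips", "jaw"):
        err = merged[seg] - merged[f"{seg}_target"]
        assert np.abs(err).max() < 0.5  # percent points, jitter-limited


def test_null_effect_targets_have_zero_mean():
    cfg = SimConfig(seed=13, n_subjects=40,
                    cooperativeness_effects={}, assertiveness_effects={},
                    valence_effects={}, arousal_effects={},
                    control_self_offsets={})
    targets = draw_condition_targets(cfg)
    perf = targets[targets["condition"] != "neutral"]
    for seg in ("brow", "eyebrow", "lips", "jaw"):
        # subject-level means are the independent units here
        subj_means = perf.groupby("subject_id")[seg].mean()
        se = subj_means.std(ddof=1) / np.sqrt(len(subj_means))
        assert abs(subj_means.mean()) < 4 * se
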