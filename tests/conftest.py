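import numpy as np
import pandas as pd
import pytest

from facekin.config import PipelineConfig, SimConfig
from facekin.mocap import MarkerTrajectorySet
from facekin.segments import DEFAULT_MARKERS


def tiny_sim_config(**overrides) -> SimConfig:
    """A fast cohort: 6 subjects, 2-s trials, mild noise."""
    defaults = dict(n_subjects=6, duration_s=2.0, seed=11,
                    jitter_sd_mm=0.3, dropout=0.02)
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return tiny_sim_config()


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory, tiny_config):
    """A small simulated cohort written to disk once per session."""
    from facekin.simulate import simulate_cohort

    out = tmp_path_factory.mktemp("cohort")
    return simulate_cohort(tiny_config, out), out


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A full tiny pipeline run shared by pipeline-level tests."""
    from facekin.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(out_dir=out, simulate=tiny_sim_config(seed=7))
    report = run_pipeline(cfg)
    return cfg, report


def small_trajectory(n_frames=5, markers=("a", "b"), sample_rate=120.0,
                     offset=(0.0, 0.0, 0.0)) -> MarkerTrajectorySet:
    """A fully valid trajectory with marker k at (k*10, 0, 0) + offset."""
    m = len(markers)
    time = np.arange(n_frames) / sample_rate
    coords = np.zeros((m, n_frames, 3))
    for k in range(m):
        coords[k, :, 0] = 10.0 * k
    coords += np.asarray(offset)
    valid = np.ones((m, n_frames), dtype=bool)
    return MarkerTrajectorySet(list(markers), time, coords, valid, sample_rate)


def face_trajectory(n_frames=4, sample_rate=120.0) -> MarkerTrajectorySet:
    """A static trajectory with the seven default facial markers."""
    from facekin.simulate import _REST

    time = np.arange(n_frames) / sample_rate
    coords = np.stack([np.broadcast_to(_REST[m], (n_frames, 3)).copy()
                       for m in DEFAULT_MARKERS])
    valid = np.ones((len(DEFAULT_MARKERS), n_frames), dtype=bool)
    return MarkerTrajectorySet(list(DEFAULT_MARKERS), time, coords, valid,
                               sample_rate)


def character_feature_table(n_subjects=8, seed=0, include_neutral=True,
                            base=50.0) -> pd.DataFrame:
    """Raw mean-length table for characters + neutral, mm scale."""
    from facekin.design import DEFAULT_CHARACTER_SCHEME

    rng = np.random.default_rng(seed)
    rows = []
    conditions = list(DEFAULT_CHARACTER_SCHEME)
    if include_neutral:
        conditions = conditions + ["neutral"]
    for i in range(n_subjects):
        for cond in conditions:
            rows.append({
                "subject_id": f"S{i:02d}", "condition": cond,
                "brow": base * (1 + 0.02 * rng.standard_normal()),
                "jaw": 1.8 * base * (1 + 0.02 * rng.standard_normal()),
            })
    return pd.DataFrame(rows)
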