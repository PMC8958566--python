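"""Synthetic motion-capture cohorts with known expressive structure.

Generates everything the analysis pipeline consumes — marker-trajectory
files, a trial manifest, and a vocal-parameter table — for a cohort of
synthetic performers. Each subject gets a rigid 7-marker face of random
overall size; each trial perturbs the four primary segments away from
their rest lengths by a designed percent offset (character, emotion or
control-self effects plus subject, latent and trial noise), rides a
speech-articulation oscillation that is identical across conditions,
sways rigidly (head motion), and is corrupted by marker jitter and
dropout. Because condition offsets scale rest lengths multiplicatively
and articulation is a zero-mean additive oscillation shared with the
neutral baseline, the designed percent change is recovered analytically
by the pipeline in the noise-free case.

Vocal parameters are linear functions of two latent expressive drivers:
trial jaw expansion (intensity) and the mean expansion of the upper-face
block (quality), plus Gaussian noise.

All randomness derives from ``config.seed`` through independent
``SeedSequence`` children, so identical configurations reproduce files
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .design import EMOTIONS, validate_scheme
from .mocap import MarkerTrajectorySet, write_manifest, write_trial, write_vocal_table
from .segments import DEFAULT_MARKERS

__all__ = [
    "FaceGeometry",
    "SimulatedCohort",
    "simulate_subject_geometry",
    "simulate_trial",
    "simulate_cohort",
    "draw_condition_targets",
    "simulate_vocal_table",
    "simulate_normalized_table",
]

SEGMENT_NAMES = ("brow", "eyebrow", "lips", "jaw")

# Rest positions at unit face scale, millimetres. x: right(+)/left(-),
# y: anterior, z: superior. The nose bridge anchors the face.
_REST = {
    "nose_bridge": np.array([0.0, 0.0, 0.0]),
    "mid_brow": np.array([0.0, 5.0, 48.0]),
    "l_eyebrow": np.array([-24.0, 0.0, 38.0]),
    "r_eyebrow": np.array([24.0, 0.0, 38.0]),
    "l_lip": np.array([-30.0, 8.0, -52.0]),
    "r_lip": np.array([30.0, 8.0, -52.0]),
    "jaw": np.array([0.0, -6.0, -95.0]),
}


@dataclass
class FaceGeometry:
    """A subject's neutral marker layout: unit-scale rest positions and
    the global face-size factor, plus the subject's articulation phase."""

    subject_id: str
    scale: float
    articulation_phase: float

    def rest(self, label: str) -> np.ndarray:
        return _REST[label]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def simulate_subject_geometry(config: SimConfig, subject_index: int
                              ) -> FaceGeometry:
    """Deterministic per-subject face geometry (size and phase)."""
    rng = _rng(config.seed, 1, subject_index)
    scale = float(max(0.3, 1.0 + config.face_scale_sd * rng.standard_normal()))
    phase = float(rng.uniform(0, 2 * np.pi))
    return FaceGeometry(subject_id=f"S{subject_index + 1:02d}", scale=scale,
                        articulation_phase=phase)


def condition_list(config: SimConfig) -> list[str]:
    """All 19 trial conditions: 9 characters, 8 emotions + neutral,
    and the control-self recording."""
    validate_scheme(config.character_scheme)
    return (list(config.character_scheme) + list(EMOTIONS) + ["neutral"]
            + ["control_self"])


def _design_offset(config: SimConfig, condition: str, segment: str) -> float:
    """Designed (noise-free) percent offset for a condition and segment."""
    scheme = config.character_scheme
    if condition == "neutral":
        return 0.0
    if condition == "control_self":
        return config.control_self_offsets.get(segment, 0.0)
    if condition in scheme:
        coop, assertive = scheme[condition]
        return (config.cooperativeness_effects.get(segment, {}).get(coop, 0.0)
                + config.assertiveness_effects.get(segment, {}).get(assertive, 0.0))
    valence, arousal = EMOTIONS[condition]
    return (config.valence_effects.get(segment, {}).get(valence, 0.0)
            + config.arousal_effects.get(segment, {}).get(arousal, 0.0))


def draw_condition_targets(config: SimConfig) -> pd.DataFrame:
    """Realized percent-change targets per (subject, condition, segment).

    target = designed offset + subject expressiveness + block latent +
    trial noise; the neutral baseline is exactly zero by construction
    (it defines the reference the pipeline normalizes against).
    """
    conditions = condition_list(config)
    rng = _rng(config.seed, 2)
    rows = []
    for i in range(config.n_subjects):
        subject = f"S{i + 1:02d}"
        u = rng.normal(0.0, config.subject_sd, size=len(SEGMENT_NAMES))
        for condition in conditions:
            q = rng.normal(0.0, config.quality_latent_sd)
            a = rng.normal(0.0, config.intensity_latent_sd)
            e = rng.normal(0.0, config.trial_noise_sd, size=len(SEGMENT_NAMES))
            row = {"subject_id": subject, "condition": condition}
            for k, seg in enumerate(SEGMENT_NAMES):
                if condition == "neutral":
                    row[seg] = 0.0
                    continue
                latent = q if seg in config.quality_segments else 0.0
                latent += a if seg in config.intensity_segments else 0.0
                row[seg] = (_design_offset(config, condition, seg)
                            + u[k] + latent + e[k])
            rows.append(row)
    return pd.DataFrame(rows)


def _rigid_head_motion(coords: np.ndarray, time: np.ndarray, config: SimConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Apply a shared slow sway (translation + small yaw) to all markers."""
    amp = config.head_sway_mm
    if amp == 0:
        return coords
    phases = rng.uniform(0, 2 * np.pi, size=4)
    f = config.head_sway_hz
    trans = np.stack([
        amp * np.sin(2 * np.pi * f * time + phases[0]),
        0.5 * amp * np.sin(2 * np.pi * f * 0.7 * time + phases[1]),
        0.8 * amp * np.sin(2 * np.pi * f * 1.3 * time + phases[2]),
    ], axis=1)                                      # (n, 3)
    yaw = 0.03 * np.sin(2 * np.pi * f * 0.5 * time + phases[3])  # radians
    c, s = np.cos(yaw), np.sin(yaw)
    x, y, z = coords[..., 0], coords[..., 1], coords[..., 2]
    rotated = np.stack([c * x - s * y, s * x + c * y, z], axis=-1)
    return rotated + trans[None, :, :]


def simulate_trial(geometry: FaceGeometry, targets: dict[str, float],
                   config: SimConfig, trial_index: int = 0,
                   condition: str = "", scale_override: float | None = None,
                   ) -> MarkerTrajectorySet:
    """One trial's marker trajectories for given segment targets (%).

    The trajectory is built at unit face scale (articulation, jitter and
    head sway included) and then multiplied by the subject's face-size
    factor, so two subjects differing only in scale produce exactly
    proportional coordinates.
    """
    n = int(round(config.duration_s * config.sample_rate))
    time = np.arange(n) / config.sample_rate
    scale = geometry.scale if scale_override is None else scale_override
    rng = _rng(config.seed, 3, trial_index)

    # per-segment length multipliers from the designed percent targets
    mult = {seg: 1.0 + targets.get(seg, 0.0) / 100.0 for seg in SEGMENT_NAMES}

    # articulation: zero-mean additive oscillation, identical process in
    # every condition of a subject (same phase, rate and amplitude)
    art = {}
    for seg, amp in config.articulation_amplitude_mm.items():
        if config.articulation_varies_by_condition:
            amp = amp * float(rng.uniform(0.5, 1.5))
        art[seg] = amp * np.sin(
            2 * np.pi * config.articulation_rate_hz * time
            + geometry.articulation_phase)
    zeros = np.zeros(n)

    rest = _REST
    coords = np.empty((len(DEFAULT_MARKERS), n, 3))
    pos = {label: np.broadcast_to(rest[label], (n, 3)).copy()
           for label in DEFAULT_MARKERS}

    # brow: mid-brow along its rest direction from the nose bridge
    u_brow = rest["mid_brow"] / np.linalg.norm(rest["mid_brow"])
    L = (np.linalg.norm(rest["mid_brow"]) * mult["brow"]
         + art.get("brow", zeros))
    pos["mid_brow"] = L[:, None] * u_brow[None, :]

    # eyebrow: symmetric horizontal spread about the fixed midline point
    mid_e = 0.5 * (rest["l_eyebrow"] + rest["r_eyebrow"])
    half_e = 0.5 * (np.linalg.norm(rest["r_eyebrow"] - rest["l_eyebrow"])
                    * mult["eyebrow"] + art.get("eyebrow", zeros))
    pos["l_eyebrow"] = mid_e[None, :] + np.outer(half_e, [-1.0, 0.0, 0.0])
    pos["r_eyebrow"] = mid_e[None, :] + np.outer(half_e, [1.0, 0.0, 0.0])

    # lips: symmetric horizontal spread, with articulation
    mid_l = 0.5 * (rest["l_lip"] + rest["r_lip"])
    half_l = 0.5 * (np.linalg.norm(rest["r_lip"] - rest["l_lip"])
                    * mult["lips"] + art.get("lips", zeros))
    pos["l_lip"] = mid_l[None, :] + np.outer(half_l, [-1.0, 0.0, 0.0])
    pos["r_lip"] = mid_l[None, :] + np.outer(half_l, [1.0, 0.0, 0.0])

    # jaw: along its rest direction from the nose bridge, with articulation
    u_jaw = rest["jaw"] / np.linalg.norm(rest["jaw"])
    Lj = np.linalg.norm(rest["jaw"]) * mult["jaw"] + art.get("jaw", zeros)
    pos["jaw"] = Lj[:, None] * u_jaw[None, :]

    for k, label in enumerate(DEFAULT_MARKERS):
        coords[k] = pos[label]

    coords = _rigid_head_motion(coords, time, config, rng)
    if config.jitter_sd_mm > 0:
        coords = coords + rng.normal(0.0, config.jitter_sd_mm, size=coords.shape)
    coords = coords * scale

    valid = np.ones((len(DEFAULT_MARKERS), n), dtype=bool)
    if config.dropout > 0:
        valid &= rng.random(valid.shape) >= config.dropout
    coords[~valid] = np.nan
    return MarkerTrajectorySet(list(DEFAULT_MARKERS), time, coords, valid,
                               config.sample_rate)


def simulate_vocal_table(targets: pd.DataFrame, config: SimConfig
                         ) -> pd.DataFrame:
    """Tidy vocal table coupled to the realized facial targets.

    Intensity driver: the trial's realized jaw percent target; quality
    driver: the mean realized target of the quality block. Control-self
    trials get no vocal rows (the calibration recording was not part of
    the vocal corpus); optionally the first ``whisper_trials`` librarian
    trials lose their rows entirely (whisper-like missingness).
    """
    rng = _rng(config.seed, 4)
    rows = []
    dropped = 0
    for _, trial in targets.iterrows():
        if trial["condition"] == "control_self":
            continue
        intensity = float(np.mean([trial[s] for s in config.intensity_segments]))
        quality = float(np.mean([trial[s] for s in config.quality_segments]))
        noise = rng.standard_normal(len(config.vocal_params))
        omit = (trial["condition"] == "librarian"
                and dropped < config.whisper_trials)
        if omit:
            dropped += 1
            continue
        for spec, z in zip(config.vocal_params, noise):
            rows.append({
                "subject_id": trial["subject_id"],
                "condition": trial["condition"],
                "parameter": spec.name,
                "value": (spec.base + spec.intensity_coef * intensity
                          + spec.quality_coef * quality + spec.noise_sd * z),
            })
    return pd.DataFrame(rows)


@dataclass
class SimulatedCohort:
    """Handles to everything a simulated cohort wrote to disk."""

    manifest: pd.DataFrame
    vocal: pd.DataFrame
    targets: pd.DataFrame
    data_dir: Path


def simulate_cohort(config: SimConfig, out_dir: str | Path) -> SimulatedCohort:
    """Write a full cohort: one TSV per trial, manifest.csv, vocal.csv.

    n_subjects x 19 trials (9 characters, 9 emotions including neutral,
    control-self). Identical config and seed reproduce identical files.
    """
    out_dir = Path(out_dir)
    data_dir = out_dir / "trials"
    data_dir.mkdir(parents=True, exist_ok=True)
    targets = draw_condition_targets(config)
    conditions = condition_list(config)
    manifest_rows = []
    trial_index = 0
    lookup = targets.set_index(["subject_id", "condition"])
    for i in range(config.n_subjects):
        geometry = simulate_subject_geometry(config, i)
        for condition in conditions:
            row = lookup.loc[(geometry.subject_id, condition)]
            seg_targets = {seg: float(row[seg]) for seg in SEGMENT_NAMES}
            traj = simulate_trial(geometry, seg_targets, config,
                                  trial_index=trial_index, condition=condition)
            path = data_dir / f"{geometry.subject_id}_{condition}.tsv"
            write_trial(traj, path)
            manifest_rows.append({
                "subject_id": geometry.subject_id,
                "condition": condition,
                "path": str(path),
            })
            trial_index += 1
    manifest = pd.DataFrame(manifest_rows)
    vocal = simulate_vocal_table(targets, config)
    write_manifest(manifest, out_dir / "manifest.csv")
    write_vocal_table(vocal, out_dir / "vocal.csv")
    targets.to_csv(out_dir / "sim_targets.csv", index=False)
    return SimulatedCohort(manifest=manifest, vocal=vocal, targets=targets,
                           data_dir=data_dir)


def simulate_normalized_table(config: SimConfig) -> pd.DataFrame:
    """Feature-level shortcut: the percent-change table the pipeline
    would recover from a noise-free capture of the same cohort.

    Skips trajectory synthesis entirely (the targets *are* the ground
    truth the multiplicative construction encodes); used for fast
    calibration and power studies. Neutral rows are dropped, as after
    normalization.
    """
    targets = draw_condition_targets(config)
    return targets[targets["condition"] != "neutral"].reset_index(drop=True)
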