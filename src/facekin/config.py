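"""Pydantic configuration models and TOML loading.

The simulation defaults below define the synthetic study conditions: a
24-subject cohort, nine characters on the 3x3 cooperativeness-by-
assertiveness grid, nine emotions (eight on the 2x2 valence-by-arousal
grid plus the neutral baseline) and a control-self trial, captured at a
nominal 120 Hz. Expressive structure follows the qualitative pattern
the analysis is designed to detect: cooperativeness/valence drive the
brow, eyebrow and lips; assertiveness/arousal drive the jaw; and the
voice couples to the same two latent dimensions.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, Field, field_validator, model_validator

from .design import DEFAULT_CHARACTER_SCHEME
from .errors import ConfigurationError

__all__ = ["VocalParamSpec", "SimConfig", "PipelineConfig", "load_config"]

LEVEL_OFFSETS_3 = ("low", "medium", "high")


class VocalParamSpec(BaseModel):
    """One synthetic vocal parameter.

    ``value = base + intensity_coef * I + quality_coef * Q + N(0, noise_sd)``
    where I is the trial's realized jaw expansion (%change) and Q the
    mean realized expansion of the brow/eyebrow/lips block.
    """

    name: str
    base: float = 0.0
    intensity_coef: float = 0.0
    quality_coef: float = 0.0
    noise_sd: float = Field(1.0, ge=0)


def _default_vocal_params() -> list[VocalParamSpec]:
    mk = VocalParamSpec
    return [
        mk(name="pitch", base=200, intensity_coef=12.0, noise_sd=65.0),
        mk(name="loudness", base=65, intensity_coef=1.0, noise_sd=5.0),
        mk(name="duration", base=20, quality_coef=-0.6, noise_sd=4.0),
        mk(name="pause_duration", base=1.5, intensity_coef=-0.05, noise_sd=0.5),
        mk(name="shimmer", base=5.0, intensity_coef=-0.04, noise_sd=0.4),
        mk(name="vocal_jitter", base=1.2, noise_sd=0.3),
        mk(name="hnr", base=15.0, noise_sd=2.0),
        mk(name="spectral_centroid", base=1500, quality_coef=-25.0, noise_sd=150.0),
        mk(name="spectral_tilt", base=-12.0, quality_coef=-0.25, noise_sd=1.5),
        mk(name="h1_h2", base=6.0, noise_sd=1.5),
        mk(name="formant_dispersion", base=1000.0, noise_sd=80.0),
        mk(name="vibrato_extent", base=0.5, noise_sd=0.2),
    ]


class SimConfig(BaseModel):
    """Synthetic-cohort generator settings.

    Effect maps are in percent-change units per factor level; condition
    offsets are applied multiplicatively to each segment's rest length,
    so the designed percent change is recovered analytically by the
    pipeline in the noise-free case.
    """

    n_subjects: int = Field(24, ge=1)
    duration_s: float = Field(10.0, gt=0)  # 120.0 emulates full-length trials
    sample_rate: float = Field(120.0, gt=0)
    seed: int = 0

    character_scheme: dict[str, tuple[str, str]] = Field(
        default_factory=lambda: dict(DEFAULT_CHARACTER_SCHEME))

    # face geometry
    face_scale_sd: float = Field(0.1, ge=0)

    # designed condition offsets, % units: factor -> segment -> level -> pct
    cooperativeness_effects: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "brow": {"low": -2.0, "medium": 0.0, "high": 2.0},
            "eyebrow": {"low": -1.5, "medium": 0.0, "high": 1.5},
            "lips": {"low": -2.5, "medium": 0.0, "high": 2.5},
        })
    assertiveness_effects: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "jaw": {"low": -2.5, "medium": 0.0, "high": 2.5},
        })
    valence_effects: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "brow": {"positive": 1.5, "negative": -1.5},
            "eyebrow": {"positive": 1.2, "negative": -1.2},
            "lips": {"positive": 2.0, "negative": -2.0},
            "jaw": {"positive": 1.0, "negative": -1.0},
        })
    arousal_effects: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "jaw": {"high": 2.0, "low": -2.0},
        })
    # contraction of the unperformed conversational control relative to
    # the performed self; magnitudes give a moderate paired effect size
    # (d_z ~ 0.6) at the default noise levels
    control_self_offsets: dict[str, float] = Field(
        default_factory=lambda: {"eyebrow": -4.0, "lips": -4.0, "jaw": -5.0})

    # random expressive structure, % units
    subject_sd: float = Field(2.0, ge=0)          # per-subject, per-segment
    trial_noise_sd: float = Field(1.5, ge=0)      # independent per trial/segment
    quality_latent_sd: float = Field(3.0, ge=0)   # shared across brow/eyebrow/lips
    intensity_latent_sd: float = Field(3.0, ge=0)  # jaw
    quality_segments: tuple[str, ...] = ("brow", "eyebrow", "lips")
    intensity_segments: tuple[str, ...] = ("jaw",)

    # speech articulation: additive oscillation, identical process across
    # conditions (amplitude mm at unit face scale, rate Hz)
    articulation_amplitude_mm: dict[str, float] = Field(
        default_factory=lambda: {"lips": 2.0, "jaw": 5.0})
    articulation_rate_hz: float = Field(4.0, gt=0)
    #: robustness switch: when True, articulation amplitude varies by
    #: condition, violating the assumption the baseline correction rests on
    articulation_varies_by_condition: bool = False

    # measurement imperfections
    dropout: float = Field(0.0, ge=0, lt=1)
    jitter_sd_mm: float = Field(0.0, ge=0)

    # head motion (rigid, does not affect segment lengths)
    head_sway_mm: float = Field(8.0, ge=0)
    head_sway_hz: float = Field(0.25, gt=0)

    vocal_params: list[VocalParamSpec] = Field(default_factory=_default_vocal_params)
    #: number of trials whose vocal rows are omitted (whisper-like missingness)
    whisper_trials: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _check(self):
        names = [v.name for v in self.vocal_params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate vocal parameter names")
        for required in ("pitch", "loudness"):
            if required not in names:
                raise ValueError(f"vocal parameter {required!r} is required")
        return self


class PipelineConfig(BaseModel):
    """End-to-end pipeline settings."""

    out_dir: Path = Path("facekin_out")
    simulate: SimConfig = Field(default_factory=SimConfig)
    baseline_condition: str = "neutral"
    min_coverage: float = Field(0.5, ge=0, le=1)
    include_supplementary_segments: bool = False
    alpha: float = Field(0.05, gt=0, lt=1)
    reml: bool = False
    outlier_z_threshold: float = Field(4.0, gt=0)
    pca_components: int = Field(2, ge=1)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a TOML file."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    # The character-name-to-cell placement is a study convention, not
    # something the library can know: a config file must state it.
    if "character_scheme" not in raw.get("simulate", {}):
        raise ConfigurationError(
            f"{path}: missing [simulate.character_scheme] block; the 3x3 "
            "character placement must be stated explicitly")
    try:
        return PipelineConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc
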