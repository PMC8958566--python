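"""Experimental design coordinates for characters and emotions.

Characters live on a 3x3 grid crossing three levels of cooperativeness
(the tendency to satisfy another's concerns) with three levels of
assertiveness (the tendency to satisfy one's own). Eight basic emotions
are grouped on a 2x2 valence-by-arousal grid from the circumplex model;
the ninth emotion, neutral, carries no coordinates and serves only as
the normalization baseline.

The character-name-to-cell placement is a configuration input: the
default below is a documented convention, not ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "LEVELS3",
    "EMOTIONS",
    "DEFAULT_CHARACTER_SCHEME",
    "emotion_grid",
    "character_grid",
    "validate_scheme",
    "condition_kind",
    "build_design_table",
    "sum_contrasts",
]

LEVELS3 = ("low", "medium", "high")

#: Emotion name -> (valence, arousal); neutral is the baseline.
EMOTIONS = {
    "happy": ("positive", "high"),
    "proud": ("positive", "high"),
    "surprised": ("positive", "high"),
    "angry": ("negative", "high"),
    "fearful": ("negative", "high"),
    "disgusted": ("negative", "high"),
    "calm": ("positive", "low"),
    "sad": ("negative", "low"),
}

BASELINE_EMOTION = "neutral"
CONTROL_SELF = "control_self"


class BaselineCondition(Exception):
    """Raised when a baseline condition is asked for design coordinates."""


# Convention, not ground truth: the attested character names placed on
# the 3x3 grid as (cooperativeness, assertiveness). The ninth slot
# ("caregiver") is freely renameable in configuration.
DEFAULT_CHARACTER_SCHEME: dict[str, tuple[str, str]] = {
    "bully": ("low", "high"),
    "hero": ("medium", "high"),
    "king": ("high", "high"),
    "loner": ("low", "medium"),
    "self": ("medium", "medium"),
    "lover": ("high", "medium"),
    "recluse": ("low", "low"),
    "librarian": ("medium", "low"),
    "caregiver": ("high", "low"),
}


def emotion_grid(name: str) -> tuple[str, str]:
    """Map an emotion name to its (valence, arousal) cell.

    Raises :class:`BaselineCondition` for the neutral baseline and
    :class:`ConfigurationError` for unknown names.
    """
    if name == BASELINE_EMOTION:
        raise BaselineCondition(
            "neutral is the baseline condition and carries no design coordinates"
        )
    try:
        return EMOTIONS[name]
    except KeyError:
        raise ConfigurationError(f"unknown emotion {name!r}") from None


def validate_scheme(scheme: dict[str, tuple[str, str]]) -> None:
    """Check that a character scheme is a complete 3x3 bijection."""
    if len(scheme) != 9:
        raise ConfigurationError(
            f"character scheme must have 9 entries, got {len(scheme)}"
        )
    cells = []
    for name, cell in scheme.items():
        cell = tuple(cell)
        if len(cell) != 2 or cell[0] not in LEVELS3 or cell[1] not in LEVELS3:
            raise ConfigurationError(
                f"character {name!r}: cell {cell!r} is not "
                "(cooperativeness, assertiveness) with levels low|medium|high"
            )
        cells.append(cell)
    if len(set(cells)) != 9:
        dupes = {c for c in cells if cells.count(c) > 1}
        raise ConfigurationError(
            f"character scheme is not a bijection; repeated cells: {sorted(dupes)}"
        )


def character_grid(name: str, scheme: dict[str, tuple[str, str]] | None = None
                   ) -> tuple[str, str]:
    """Map a character name to its (cooperativeness, assertiveness) cell."""
    scheme = DEFAULT_CHARACTER_SCHEME if scheme is None else scheme
    validate_scheme(scheme)
    try:
        return tuple(scheme[name])
    except KeyError:
        raise ConfigurationError(f"unknown character {name!r}") from None


def condition_kind(name: str, scheme: dict[str, tuple[str, str]] | None = None
                   ) -> str:
    """Classify a condition label as character | emotion | baseline | control_self."""
    scheme = DEFAULT_CHARACTER_SCHEME if scheme is None else scheme
    if name == CONTROL_SELF:
        return "control_self"
    if name == BASELINE_EMOTION:
        return "baseline"
    if name in scheme:
        return "character"
    if name in EMOTIONS:
        return "emotion"
    raise ConfigurationError(f"unlabeled condition {name!r}")


def sum_contrasts(levels: tuple[str, ...]) -> pd.DataFrame:
    """Sum-to-zero (deviation) contrast codes for an ordered factor.

    Returns a (n_levels x n_levels-1) frame whose columns each sum to
    zero; the last level is the implicitly coded one. Sum-to-zero
    coding keeps type III tests well-defined in unbalanced designs.
    """
    k = len(levels)
    mat = np.vstack([np.eye(k - 1), -np.ones((1, k - 1))])
    return pd.DataFrame(mat, index=list(levels),
                        columns=[f"c{i + 1}" for i in range(k - 1)])


def _attach_factor(df: pd.DataFrame, factor: str, levels: tuple[str, ...]) -> pd.DataFrame:
    codes = sum_contrasts(levels)
    for col in codes.columns:
        df[f"{factor}_{col}"] = df[factor].map(codes[col])
    return df


def build_design_table(manifest: pd.DataFrame,
                       scheme: dict[str, tuple[str, str]] | None = None,
                       ) -> pd.DataFrame:
    """Attach design coordinates and contrast codings to a trial manifest.

    Adds a ``kind`` column, factor-level columns (cooperativeness /
    assertiveness for characters, valence / arousal for emotions) and
    sum-to-zero contrast columns for each factor. Baseline and
    control-self rows keep NaN factor levels.
    """
    scheme = DEFAULT_CHARACTER_SCHEME if scheme is None else scheme
    validate_scheme(scheme)
    df = manifest.copy()
    kinds, coop, assertive, valence, arousal = [], [], [], [], []
    for name in df["condition"]:
        kind = condition_kind(name, scheme)
        kinds.append(kind)
        if kind == "character":
            c, a = scheme[name]
            coop.append(c); assertive.append(a)
            valence.append(np.nan); arousal.append(np.nan)
        elif kind == "emotion":
            v, r = EMOTIONS[name]
            valence.append(v); arousal.append(r)
            coop.append(np.nan); assertive.append(np.nan)
        else:
            coop.append(np.nan); assertive.append(np.nan)
            valence.append(np.nan); arousal.append(np.nan)
    df["kind"] = kinds
    df["cooperativeness"] = coop
    df["assertiveness"] = assertive
    df["valence"] = valence
    df["arousal"] = arousal
    _attach_factor(df, "cooperativeness", LEVELS3)
    _attach_factor(df, "assertiveness", LEVELS3)
    _attach_factor(df, "valence", ("positive", "negative"))
    _attach_factor(df, "arousal", ("high", "low"))
    return df


def cell_counts(design: pd.DataFrame, factors: tuple[str, str]) -> pd.DataFrame:
    """Cross-tabulated trial counts for a pair of design factors."""
    sub = design.dropna(subset=list(factors))
    return sub.groupby(list(factors), observed=True).size().unstack(fill_value=0)
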