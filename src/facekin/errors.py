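"""Exception hierarchy shared across the package."""


class FacekinError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FacekinError):
    """A file does not follow the declared dialect (bad header, ragged rows,
    non-monotonic time). The message names the offending line or column."""


class SchemaError(FacekinError):
    """A tidy table is missing required columns or has unparseable values."""


class ConfigurationError(FacekinError):
    """An analysis configuration is inconsistent (unknown marker, duplicate
    segment name, incomplete character scheme, ...)."""


class UndefinedFeatureError(FacekinError):
    """A trial-level feature cannot be computed (too few valid frames)."""

    def __init__(self, segment: str, message: str | None = None):
        self.segment = segment
        super().__init__(message or f"feature undefined for segment {segment!r}")


class NormalizationError(FacekinError):
    """Baseline normalization is impossible for a (subject, segment) pair."""

    def __init__(self, subject_id: str, segment: str, message: str | None = None):
        self.subject_id = subject_id
        self.segment = segment
        super().__init__(
            message
            or f"cannot normalize segment {segment!r} for subject {subject_id!r}"
        )


class DegenerateModelError(FacekinError):
    """A statistical model cannot be fit (zero-variance response,
    rank-deficient design)."""
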