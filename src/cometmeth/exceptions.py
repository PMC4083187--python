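"""Exception hierarchy for the methylation-sensitive comet assay pipeline.

Every error raised by the package derives from :class:`CometMethError` so
callers can catch pipeline failures without masking programming errors.
"""


class CometMethError(Exception):
    """Base class for all package errors."""


class ParameterError(CometMethError, ValueError):
    """A simulation or analysis parameter violates its invariant.

    The message names the offending field.
    """


class DomainError(CometMethError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class UndefinedRatioError(DomainError):
    """The MspI denominator is zero — the digestion signal is absent.

    In the wet assay this corresponds to a failed MspI digestion; the
    HpaII/MspI ratio (and hence % CpG methylation) is undefined.
    """


class InferenceError(CometMethError):
    """Bootstrap inference failed (too many degenerate replicates)."""


class ConfigurationError(CometMethError, ValueError):
    """Two results being combined were built with incompatible settings."""


class SchemaError(CometMethError, ValueError):
    """A table failed validation against the expected CSV schema.

    Carries the offending line numbers (1-based, header = line 1) when they
    are known.
    """

    def __init__(self, message: str, lines: list[int] | None = None):
        self.lines = lines or []
        if self.lines:
            message = f"{message} (lines: {', '.join(map(str, self.lines))})"
        super().__init__(message)


class GeometryError(CometMethError, ValueError):
    """A synthetic comet does not fit inside the requested image frame."""


class UnscorableImageError(CometMethError):
    """No comet could be located in the image (blank or sub-background)."""
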