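"""Exception types shared across the package."""


class AvakitError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AvakitError, ValueError):
    """A generator or analysis parameter violates its contract."""


class ProtocolError(AvakitError, ValueError):
    """A stimulus protocol is malformed (overlap, ordering, bounds)."""


class AlignmentError(AvakitError, ValueError):
    """Two traces that must share a time base have different lengths."""


class DegenerateBaselineError(AvakitError, ValueError):
    """The sliding-percentile baseline F0 is zero or negative somewhere."""


class NormalizationError(AvakitError, ValueError):
    """A distribution cannot be normalized on the requested support."""


class EmptyTailError(AvakitError, ValueError):
    """No observations at or above x_min; nothing to fit."""


class DegenerateSampleError(AvakitError, ValueError):
    """All observations identical; model comparison undefined."""


class UndefinedFieldError(AvakitError, ValueError):
    """A receptive-field statistic is undefined (all-nonpositive RF)."""


class MissingRfError(AvakitError, KeyError):
    """An ensemble member has no receptive field."""


class ConfigError(AvakitError, ValueError):
    """Pipeline configuration invalid."""


class StageError(AvakitError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
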