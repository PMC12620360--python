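"""Typed exceptions shared across the package."""


class EarAttnError(Exception):
    """Base class for all package errors."""


class UnknownConditionError(EarAttnError, ValueError):
    """Condition label is not one of {'stress', 'relax'}."""


class InvalidConfigError(EarAttnError, ValueError):
    """A configuration object violates its invariants."""


class RecordingReadError(EarAttnError, ValueError):
    """A recording file is missing, malformed, or lacks required metadata."""


class MissingChannelError(EarAttnError, KeyError):
    """A required channel label is absent from a recording or epoch set."""


class FilterDesignError(EarAttnError, ValueError):
    """Requested filter bands are incompatible with the sampling rate."""


class TooShortError(EarAttnError, ValueError):
    """Recording is shorter than the requested epoch length."""


class DegenerateDataError(EarAttnError, ValueError):
    """Statistical input carries no usable information (e.g. all-zero diffs)."""


class UnsupportedVariantError(EarAttnError, ValueError):
    """Operation requires a model component this variant does not have."""
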