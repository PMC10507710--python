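"""Exception hierarchy for hapblock."""


class HapblockError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HapblockError):
    """Input data violates a structural invariant."""


class ParseError(HapblockError):
    """A file could not be parsed; message names the offending line."""


class ParameterError(HapblockError):
    """A parameter is outside its admissible range."""


class MonomorphicError(HapblockError):
    """An LD statistic was requested for a monomorphic locus."""


class EmptyResultError(HapblockError):
    """An operation removed every record."""


class ModelFitError(HapblockError):
    """A model fit failed (rank deficiency, non-PSD kernel, divergence)."""
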