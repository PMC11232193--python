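"""Exception hierarchy shared across the package."""


class CernetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CernetError):
    """A text input file violates the expected layout (names the offending line)."""


class EmptyInputError(CernetError):
    """An input file or table contains no usable records."""


class KindMismatchError(CernetError, TypeError):
    """Association tables of different kinds were combined."""


class DegenerateInputError(CernetError):
    """Zero-variance vector or vanishing denominator in a correlation."""


class InsufficientSamplesError(CernetError):
    """Fewer samples than the statistic's minimum (partial correlation needs n >= 4)."""


class GeneLookupError(CernetError, LookupError):
    """A triplet references a gene absent from the expression matrix."""


class SampleLookupError(CernetError, LookupError):
    """A requested sample id is not present."""


class NotEstimableError(CernetError):
    """A survival model cannot be fit (no events, empty arm, separation)."""


class ConfigError(CernetError):
    """An invalid simulation or pipeline configuration."""
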