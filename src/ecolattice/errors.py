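"""Exception hierarchy shared across the pipeline stages."""


class EcolatticeError(Exception):
    """Base class for all package errors."""


class ConfigError(EcolatticeError):
    """Invalid configuration (non-positive dimensions, bad dates, ...)."""


class ValidationError(EcolatticeError):
    """Malformed or inconsistent input data."""


class DegenerateInputError(EcolatticeError):
    """Input lacks the variation an operation requires (e.g. constant values)."""


class RecodeError(EcolatticeError):
    """A raw land-use code has no entry in the recode mapping."""


class InsufficientDataError(EcolatticeError):
    """Too little data for the operation (e.g. < 2 calendar years)."""


class NumericalConditioningError(EcolatticeError):
    """A covariance or precision matrix is numerically singular."""


class AssemblyError(EcolatticeError):
    """A precision matrix came out non-positive-definite."""


class GenerationError(EcolatticeError):
    """Synthetic generation produced pathological values (mu overflow)."""


class ConvergenceError(EcolatticeError):
    """Inference failed to converge; offending quantities are listed."""
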