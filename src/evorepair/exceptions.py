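"""Exception hierarchy.

All validation failures raise subclasses of :class:`EvoRepairError` so the
command-line layer can catch one type and exit nonzero with a message.
"""


class EvoRepairError(Exception):
    """Base class for all package errors."""


class ValidationError(EvoRepairError, ValueError):
    """Malformed or inconsistent input."""


class ConfigError(ValidationError):
    """Invalid configuration value (alpha outside (0,1), even span, ...)."""


class SizingError(ValidationError):
    """Requested genes do not fit on the supplied contigs."""


class CoordinateError(ValidationError):
    """Position outside the genome, or mismatched window grids."""


class NormalizationError(ValidationError):
    """Depth track cannot be normalized (all-zero depths)."""


class InsufficientDataError(ValidationError):
    """Fewer usable observations than the estimator requires."""


class UndefinedRatioError(ValidationError):
    """Competition ratio undefined because fluorescent events are zero."""


class PlanningError(ValidationError):
    """Bottleneck target is infeasible for the given final population size."""


class DomainError(ValidationError):
    """Argument outside the mathematical domain of an operation."""
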