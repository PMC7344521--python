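"""Exception hierarchy.

Every error raised by the package derives from :class:`SpinemetryError`, so
callers (and the CLI) can distinguish configuration problems (exit code 2)
from data problems (exit code 3).
"""


class SpinemetryError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SpinemetryError, ValueError):
    """A function argument or configuration value is out of its valid range."""


class InvalidInputError(SpinemetryError, ValueError):
    """An input data object violates a precondition (too short, missing, ...)."""


class AlignmentError(SpinemetryError):
    """Two time series cannot be brought onto a common grid (no overlap, grid mismatch)."""


class ConfigurationError(SpinemetryError):
    """A configuration object is internally inconsistent."""


class DataError(SpinemetryError):
    """A dataset is unusable for the requested analysis."""


class UndefinedStatisticError(SpinemetryError):
    """A statistic is undefined for the given data (zero variance, etc.)."""


class InfeasibleQueryError(SpinemetryError):
    """A power/sample-size query has no solution below the configured cap."""
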