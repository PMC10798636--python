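"""Exception hierarchy shared by all nutriq modules.

Everything derives from :class:`NutriqError` so callers can catch the
package's failures with a single except clause while still distinguishing
bad user input (``ValueError`` family) from failed analyses
(``RuntimeError`` family).
"""


class NutriqError(Exception):
    """Base class for all errors raised by nutriq."""


class DomainError(NutriqError, ValueError):
    """A parameter or observation lies outside its mathematical domain."""


class InfeasibleObservationError(DomainError):
    """An observed growth rate is incompatible with the model (λ ≥ λmax)."""


class ConfigError(NutriqError, ValueError):
    """A configuration file or option is malformed or inconsistent."""


class FormatError(NutriqError, ValueError):
    """A tabular input file violates its schema (names file/line/column)."""


class DataError(NutriqError, ValueError):
    """Input data values violate a precondition (e.g. non-positive OD)."""


class InsufficientDataError(DataError):
    """Too few data points for the requested fit."""


class StatisticsError(NutriqError, ValueError):
    """A statistic is undefined for the given input (n too small, constant)."""


class AnalysisError(NutriqError, RuntimeError):
    """A multi-step analysis could not be completed."""


class FitError(AnalysisError):
    """A model fit failed or is degenerate."""


class NoShiftError(AnalysisError):
    """No growth-rate slowdown (diauxic shift onset) was detected."""


class NoRegrowthError(AnalysisError):
    """No post-shift exponential regrowth was detected."""


class SelectionError(AnalysisError):
    """No data window satisfied the selection criteria."""
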