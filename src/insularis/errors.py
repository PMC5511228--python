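"""Exception hierarchy for insularis.

Every error raised by the package derives from :class:`InsularisError` so
callers (and the CLI) can catch package failures in one clause.
"""


class InsularisError(Exception):
    """Base class for all insularis errors."""


class FormatError(InsularisError):
    """An input table is malformed (missing columns, bad values)."""


class EmptyInputError(InsularisError):
    """An input file or table contains no records."""


class IntegrityError(InsularisError):
    """Referential integrity violated in strict mode (unknown island/species)."""


class EmptyGroupError(InsularisError):
    """A species-group filter selected zero species."""


class DegenerateInputError(InsularisError):
    """Input carries no signal for the requested fit (e.g. all-zero richness)."""


class ConvergenceError(InsularisError):
    """Nonlinear fit failed to converge; carries the best parameters seen."""

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class UndefinedPairError(InsularisError):
    """A beta-diversity comparison is undefined (pooled richness is zero)."""


class UndefinedMatrixError(InsularisError):
    """A matrix statistic is undefined for this shape (e.g. 1x1 NODF)."""


class ConfigError(InsularisError):
    """A run or generator configuration is invalid or infeasible."""
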