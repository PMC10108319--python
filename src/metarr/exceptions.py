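"""Exception hierarchy for metarr.

All package-specific errors derive from :class:`MetarrError` so callers can
catch the whole family with one clause.
"""


class MetarrError(Exception):
    """Base class for all metarr errors."""


class DomainError(MetarrError):
    """A quantity violates the ratio-scale requirements of the log response
    ratio (e.g. a nonpositive group mean)."""


class MissingSDError(MetarrError):
    """An operation that needs an observed standard deviation was given a
    record whose SD is missing."""


class DegenerateVarianceError(MetarrError):
    """A sampling variance of exactly zero was produced; a zero diagonal in
    the sampling (co)variance matrix is singular and cannot enter a fit."""


class NoCompleteRecordsError(MetarrError):
    """Pooling of coefficients of variation was requested but no record
    reports the required SDs."""


class StrategyPreconditionError(MetarrError):
    """A missing-SD strategy was applied to a dataset that violates its
    preconditions (e.g. the no-missing reference on data with missing SDs)."""


class ConvergenceError(MetarrError):
    """REML optimisation failed to converge after bounded restarts."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SingularityError(MetarrError):
    """The implied marginal covariance matrix is singular or not positive
    definite."""


class SingleEffectError(MetarrError):
    """A summary that needs at least two effect sizes was given one."""


class UndefinedHeterogeneityError(MetarrError):
    """A heterogeneity ratio is undefined because both variance components
    in the ratio are zero."""


class SchemaError(MetarrError):
    """An input table does not match the expected column schema."""


class ConfigError(MetarrError):
    """A simulation or run configuration contains invalid fields."""
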