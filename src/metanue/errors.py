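"""Exception hierarchy shared across the pipeline stages."""


class MetanueError(Exception):
    """Base class for all package errors."""


class SchemaError(MetanueError):
    """A required column is missing or mis-typed in an input table."""


class ValidationError(MetanueError):
    """Row-level data violate a hard invariant (e.g. replicate count < 2)."""


class ImputationError(MetanueError):
    """Dispersion imputation is impossible (no reported SDs at all)."""


class DegenerateScaleError(MetanueError):
    """A covariate selected for unit-variance scaling is constant."""


class CollinearityError(MetanueError):
    """The design matrix is rank deficient or moderators are too correlated."""


class ConvergenceError(MetanueError):
    """The variance-component optimizer failed to converge."""


class UnderdeterminedError(MetanueError):
    """Fewer effects than fixed-effect coefficients."""


class NoDataError(MetanueError):
    """An operation received an empty collection."""


class ContractError(MetanueError):
    """Arguments are mutually inconsistent (e.g. dimension mismatch)."""


class DomainError(MetanueError):
    """A value is outside the mathematical domain of a formula."""
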