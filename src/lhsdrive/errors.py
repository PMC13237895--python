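"""Exception hierarchy shared across the package."""


class LhsdriveError(Exception):
    """Base class for all package errors."""


class ValidationError(LhsdriveError, ValueError):
    """Invalid input data or configuration."""


class StabilityError(LhsdriveError, ValueError):
    """Coupling matrix with spectral radius >= 1: the linear spillover
    system has no stable fixed point and must not be inverted."""


class UndefinedStatisticError(LhsdriveError, ValueError):
    """A statistic whose defining ratio is 0/0 on this input
    (e.g. weighted kappa under all-constant marginals)."""
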