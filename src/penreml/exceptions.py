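"""Exception hierarchy.

All errors raised by penreml derive from :class:`PenremlError` so callers can
catch the package's failures with a single except clause.  ``BoundaryError``
is special: it signals that a covariance matrix hit the edge of the parameter
space (non positive definite), which optimizers treat as an infinitely bad
objective rather than a hard failure.
"""


class PenremlError(Exception):
    """Base class for all penreml errors."""


class InvalidInputError(PenremlError, ValueError):
    """Malformed or inconsistent input (shapes, non-finite values, singular)."""


class DomainError(PenremlError, ValueError):
    """A quantity lies outside its mathematical domain.

    For example a canonical eigenvalue outside [0, 1] beyond numerical
    tolerance, meaning sigma_G is not a valid genetic fraction of sigma_P.
    """


class BoundaryError(PenremlError, ArithmeticError):
    """A covariance matrix required to be positive definite is not.

    Raised when a likelihood or penalty is evaluated at the boundary of the
    parameter space; optimization code converts this to a -inf objective.
    """


class DegenerateTraitError(PenremlError, ValueError):
    """A trait has zero variance, so correlations are undefined."""


class ConfigurationError(PenremlError, ValueError):
    """An analysis configuration is invalid (e.g. a penalty without the
    baseline quantities it needs, or a degenerate cross-validation split)."""
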