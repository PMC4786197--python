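"""Exception hierarchy for the package."""


class NavfitError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(NavfitError):
    """A rate parameter violates its domain (e.g. non-positive)."""


class RateEvaluationError(NavfitError):
    """A rate expression overflowed or produced a non-finite value."""


class SchemeDefinitionError(NavfitError):
    """A kinetic scheme is malformed (missing reverse edge, unknown label...)."""


class GeneratorError(NavfitError):
    """A generator matrix violates conservation or positivity."""


class EquilibriumError(NavfitError):
    """The stationary distribution is not unique (reducible/defective Q)."""


class DetailedBalanceError(NavfitError):
    """Detailed balance is undefined or violated on a cycle."""


class ReversibilityError(NavfitError):
    """Cycle closure is over- or under-constrained."""


class ProtocolDefinitionError(NavfitError):
    """A voltage protocol is malformed or names an unknown readout."""


class ReadoutUndefinedError(NavfitError):
    """A summary statistic is undefined for the given trace."""


class FitFailureError(NavfitError):
    """A curve fit failed to converge; carries the best iterate."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class DegenerateRegressionError(NavfitError):
    """A regression problem is rank-deficient (e.g. identical voltages)."""


class AlignmentError(NavfitError):
    """Dataset and simulation readouts do not align 1:1."""


class InvalidStartError(NavfitError):
    """The optimization cannot start (infinite cost at the initial point)."""


class DatasetFormatError(NavfitError):
    """A delimited dataset or parameter file is malformed."""
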