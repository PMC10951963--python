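"""Exception hierarchy for model specification and numerical failures."""


class VariationalLaplaceError(Exception):
    """Base class for all errors raised by this package."""


class InputError(VariationalLaplaceError, ValueError):
    """Malformed or dimensionally inconsistent user input."""


class EvaluationError(VariationalLaplaceError):
    """A model function returned a non-finite value.

    Carries the offending parameter vector (and, where known, the parameter
    index being perturbed) so the caller can diagnose where the model breaks.
    """

    def __init__(self, message, beta=None, index=None):
        super().__init__(message)
        self.beta = beta
        self.index = index


class DegenerateModelError(VariationalLaplaceError):
    """A constructed matrix (e.g. the noise precision) is numerically singular."""


class DecompositionError(VariationalLaplaceError):
    """A covariance/precision matrix failed a symmetric positive-definite factorisation."""


class ConditioningError(VariationalLaplaceError):
    """A curvature matrix is too ill-conditioned to produce a stable update."""


class DomainError(VariationalLaplaceError):
    """A model field was evaluated outside its physical domain (e.g. negative volume)."""


class IntegrationError(VariationalLaplaceError):
    """Numerical integration of a state-space model produced non-finite states."""

    def __init__(self, message, time=None, state=None):
        super().__init__(message)
        self.time = time
        self.state = state
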