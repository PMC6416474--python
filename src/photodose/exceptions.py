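"""Exception hierarchy."""


class PhotodoseError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PhotodoseError, ValueError):
    """A physical or numerical parameter is outside its valid domain."""


class InvalidStateError(PhotodoseError, ValueError):
    """A kinetic state vector violates its invariants (e.g. negativity)."""


class IntegrationFailure(PhotodoseError, RuntimeError):
    """Adaptive ODE integration could not proceed (step-size underflow).

    Carries ``t_reached``, the last time the integrator accepted.
    """

    def __init__(self, message: str, t_reached: float = float("nan")):
        super().__init__(message)
        self.t_reached = t_reached


class FitFailure(PhotodoseError, RuntimeError):
    """Nonlinear least-squares did not converge to an acceptable residual."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class InsufficientDataError(PhotodoseError, ValueError):
    """Too few usable data points for the requested fit."""


class TransportError(PhotodoseError, RuntimeError):
    """Internal consistency failure inside the photon-transport kernel."""
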