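"""Exception hierarchy for kindisc."""


class KindiscError(Exception):
    """Base class for all kindisc errors."""


class ModelDefinitionError(KindiscError):
    """A kinetic model references undeclared species or parameters."""


class UnsupportedRateLawError(KindiscError):
    """A rate-law form outside the supported set was requested."""


class SimulationError(KindiscError):
    """The ODE integrator failed before reaching the end of the grid.

    ``time_reached`` carries the last time point the integrator attained.
    """

    def __init__(self, message: str, time_reached: float | None = None):
        super().__init__(message)
        self.time_reached = time_reached


class IncompatibleTimeCourseError(KindiscError):
    """Two time courses do not share a grid and species ordering."""


class DegenerateWeightingError(KindiscError):
    """A weighted L2 norm was requested with a zero-mean observable."""


class InfeasibleBoundsError(KindiscError):
    """Trial-vector generation could not produce an in-bounds vector."""


class EstimationFailureError(KindiscError):
    """No member of the DE population produced a feasible simulation."""


class SloppinessWarning(UserWarning):
    """The Fisher information matrix is ill-conditioned; standard errors
    are unreliable (parameter 'sloppiness')."""
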