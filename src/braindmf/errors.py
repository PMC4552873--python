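"""Exception hierarchy shared across the package."""


class BrainDMFError(Exception):
    """Base class for all braindmf errors."""


class FormatError(BrainDMFError):
    """Malformed input file (wrong shape, non-numeric, empty)."""


class ValidationError(BrainDMFError):
    """A domain object violates one of its invariants."""


class ParameterError(ValidationError):
    """A configuration or generator parameter is out of its valid range."""


class CalibrationError(BrainDMFError):
    """Feedback inhibition control failed to reach the target rate."""

    def __init__(self, message: str, worst_node: int | None = None):
        super().__init__(message)
        self.worst_node = worst_node


class StabilityError(BrainDMFError):
    """The Jacobian at the operating point has a non-negative eigenvalue."""


class SimulationError(BrainDMFError):
    """Stochastic integration produced NaN/Inf."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class DegenerateDataError(BrainDMFError):
    """Data carries no usable variance (all-constant, zero covariance)."""
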