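"""Exception hierarchy."""


class VoltmemError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(VoltmemError, ValueError):
    """A physically meaningless parameter (non-positive tau, zero valence, ...)."""


class AssemblyError(VoltmemError):
    """A membrane model could not be assembled (e.g. unresolvable ion species)."""


class ReductionError(VoltmemError):
    """Fast reduction requested for a model containing slow gates."""


class SolverError(VoltmemError):
    """The ODE integrator failed; carries the time of failure when known."""

    def __init__(self, message: str, time_ms: float | None = None):
        super().__init__(message)
        self.time_ms = time_ms


class ChannelMLError(VoltmemError):
    """Unsupported or malformed channel kinetics document."""
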