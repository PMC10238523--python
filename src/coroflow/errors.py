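"""Exception hierarchy for coroflow."""


class CoroflowError(Exception):
    """Base class for all coroflow errors."""


class SchemaError(CoroflowError):
    """A patient/cohort config is structurally invalid (missing or unknown field, bad units)."""


class InvariantError(CoroflowError):
    """A measurement set violates a physiological invariant (e.g. DBP >= SBP).

    Deliberately not a ValueError subclass: pydantic would otherwise absorb it
    into its own ValidationError and the failed rule would be buried."""


class GenerationError(CoroflowError):
    """The synthetic cohort generator was given an infeasible field distribution."""


class DomainError(CoroflowError, ValueError):
    """A derivation formula was evaluated outside its mathematical domain."""


class SimulationError(CoroflowError):
    """The ODE integration produced non-finite values; message names the component."""


class ConvergenceError(CoroflowError):
    """Periodic steady state was not reached within the cycle budget."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class TuningError(CoroflowError):
    """Parameter tuning failed to reach the measurement targets."""

    def __init__(self, message, best_residuals=None):
        super().__init__(message)
        self.best_residuals = dict(best_residuals or {})


class MetricsError(CoroflowError):
    """A metric was requested on waveforms that do not support it (e.g. open PV loop)."""
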