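"""Exception hierarchy for the peepabsorb package."""


class PeepAbsorbError(Exception):
    """Base class for all package errors."""


class InvalidSettingsError(PeepAbsorbError):
    """Ventilator settings violate an invariant (e.g. non-positive expiratory time)."""


class InvalidModelError(PeepAbsorbError):
    """Lung-model parameters violate an invariant."""


class StepSizeError(PeepAbsorbError):
    """Sampling interval too coarse for the smallest compartment time constant."""


class CalibrationError(PeepAbsorbError):
    """Compartment calibration targets unreachable within parameter bounds."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class CorruptedManeuverError(PeepAbsorbError):
    """Flow exceeds the zero-flow tolerance inside an occlusion."""


class DegenerateMechanicsError(PeepAbsorbError):
    """Plateau pressure does not exceed total PEEP; mechanics undefined."""


class InconsistentInputsError(PeepAbsorbError):
    """Measured pressures are mutually inconsistent (e.g. negative auto-PEEP)."""


class ManeuverRejectedError(PeepAbsorbError):
    """Expiration segment unusable for a flow-volume loop."""


class UndeterminableError(PeepAbsorbError):
    """Flow-limitation verdict cannot be established (e.g. empty loop overlap)."""


class UndefinedPercentageError(PeepAbsorbError):
    """Applied PEEP is non-positive; percentage change undefined."""


class IneligiblePatientError(PeepAbsorbError):
    """Patient does not meet the auto-PEEP enrollment threshold."""


class ConfigError(PeepAbsorbError):
    """Invalid configuration value; message names the offending field."""


class SchemaError(PeepAbsorbError):
    """Input table does not match the expected column schema."""


class DegenerateModelError(PeepAbsorbError):
    """Statistical model cannot be fitted (empty class, single value, ...)."""
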