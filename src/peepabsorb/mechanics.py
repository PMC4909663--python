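"""Respiratory-mechanics measurements from ventilator waveforms.

Implements the bedside computations: occlusion plateau pressures, compliance
``VT / (Pplat - PEEPtot)``, resistance ``(Ppk - Pplat) / inspiratory flow``,
auto-PEEP ``PEEPtot - applied PEEP``, and the triplicate repeatability rule
(every measurement within 10 % of the triplicate mean, 1 cmH2O tolerated).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CorruptedManeuverError,
    DegenerateMechanicsError,
    InconsistentInputsError,
)
from .ventilation import WaveformRecording

__all__ = [
    "MechanicsMeasurement",
    "measure_plateau",
    "measure_peak_pressure",
    "compute_mechanics",
    "validate_triplicate",
    "check_persistent_expiratory_flow",
]


@dataclass
class MechanicsMeasurement:
    """Triplicate-averaged pressures and derived mechanics for one phase."""

    ppk: float                    # cmH2O, mean peak airway pressure
    pplat: float                  # cmH2O, mean end-inspiratory plateau
    peep_tot: float               # cmH2O, mean end-expiratory occlusion plateau
    applied_peep: float           # cmH2O
    auto_peep: float              # cmH2O, peep_tot - applied_peep
    compliance: float             # L/cmH2O
    elastance: float              # cmH2O/L
    resistance: float             # cmH2O.s/L
    valid: bool = True            # triplicate repeatability for all pressures
    ppk_triplicate: tuple = field(default_factory=tuple)
    pplat_triplicate: tuple = field(default_factory=tuple)
    peep_tot_triplicate: tuple = field(default_factory=tuple)


def measure_plateau(segment: WaveformRecording, window: float = 0.5,
                    zero_flow_tol: float = 0.02,
                    slope_tol: float = 0.05) -> float:
    """Mean airway pressure over the final ``window`` seconds of an occlusion.

    Raises CorruptedManeuverError when flow inside the occlusion exceeds the
    zero-flow tolerance.  Attaches no convergence flag to the return value;
    non-convergence (|slope| > ``slope_tol``) raises a warning annotation at
    simulation time and is re-checked here via the fitted slope.
    """
    if len(segment.time) == 0:
        raise CorruptedManeuverError("empty occlusion segment")
    if np.max(np.abs(segment.flow)) > zero_flow_tol:
        raise CorruptedManeuverError(
            f"flow magnitude {np.max(np.abs(segment.flow)):.3f} L/s exceeds "
            f"zero-flow tolerance {zero_flow_tol} L/s inside occlusion"
        )
    duration = segment.time[-1] - segment.time[0] + 1.0 / segment.sample_rate
    window = min(window, duration)
    t_end = segment.time[-1]
    m = segment.time >= t_end - window + 1e-9
    pressure = segment.airway_pressure[m]
    # convergence check over a longer stretch so sensor noise does not
    # masquerade as a residual slope: require the fitted slope to exceed both
    # the tolerance and three times its own standard error
    m_slope = segment.time >= t_end - min(2.0, duration) + 1e-9
    t_s = segment.time[m_slope]
    p_s = segment.airway_pressure[m_slope]
    if len(p_s) >= 3:
        (slope, intercept), cov = np.polyfit(t_s, p_s, 1, cov=True)
        se = float(np.sqrt(cov[0, 0]))
        if abs(slope) > max(slope_tol, 3.0 * se):
            import warnings
            warnings.warn(
                f"occlusion plateau not converged (|dP/dt| = {abs(slope):.3f} "
                "cmH2O/s at occlusion end)",
                stacklevel=2,
            )
    return float(pressure.mean())


def measure_peak_pressure(breath: WaveformRecording) -> float:
    """Peak airway pressure over the inspiratory phase of a breath."""
    m = breath.phase == "insp"
    if not m.any():
        raise CorruptedManeuverError("breath contains no inspiratory samples")
    return float(breath.airway_pressure[m].max())


def compute_mechanics(ppk: float, pplat: float, peep_tot: float,
                      applied_peep: float, tidal_volume: float,
                      inspiratory_flow: float,
                      valid: bool = True,
                      triplicates: dict | None = None,
                      autopeep_tol: float = 0.5) -> MechanicsMeasurement:
    """Derive compliance, elastance, resistance and auto-PEEP from the
    triplicate-averaged pressures."""
    if inspiratory_flow <= 0:
        raise InconsistentInputsError("inspiratory flow must be positive")
    if pplat <= peep_tot:
        raise DegenerateMechanicsError(
            f"Pplat ({pplat:.2f}) must exceed PEEPtot ({peep_tot:.2f})"
        )
    auto_peep = peep_tot - applied_peep
    if auto_peep < -autopeep_tol:
        raise InconsistentInputsError(
            f"negative auto-PEEP {auto_peep:.2f} cmH2O: PEEPtot below applied PEEP"
        )
    auto_peep = max(auto_peep, 0.0)
    compliance = tidal_volume / (pplat - peep_tot)
    resistance = (ppk - pplat) / inspiratory_flow
    triplicates = triplicates or {}
    return MechanicsMeasurement(
        ppk=ppk, pplat=pplat, peep_tot=peep_tot, applied_peep=applied_peep,
        auto_peep=auto_peep, compliance=compliance,
        elastance=1.0 / compliance, resistance=resistance, valid=valid,
        ppk_triplicate=tuple(triplicates.get("ppk", ())),
        pplat_triplicate=tuple(triplicates.get("pplat", ())),
        peep_tot_triplicate=tuple(triplicates.get("peep_tot", ())),
    )


def validate_triplicate(values) -> bool:
    """Repeatability rule: every measurement within 10 % of the triplicate
    mean, with an absolute difference of 1 cmH2O tolerated."""
    values = np.asarray(values, dtype=float)
    if values.shape != (3,):
        raise ValueError("exactly three values required")
    mean = values.mean()
    tol = max(0.10 * abs(mean), 1.0)
    return bool(np.all(np.abs(values - mean) <= tol + 1e-12))


def check_persistent_expiratory_flow(recording: WaveformRecording,
                                     zero_flow_tol: float = 0.02) -> bool:
    """True when expiratory flow persists at the start of every inspiration.

    Requires at least three steady-state breaths; inspects the last expiratory
    sample before each inspiration after the first.
    """
    breaths = recording.intervals("breath")
    if len(breaths) < 3:
        raise ValueError("need at least three annotated breaths")
    exp_mask = np.isin(recording.phase, ("exp",))
    ok = True
    for b in breaths:
        m = b.mask(recording.time) & exp_mask
        if not m.any():
            return False
        last_exp_flow = recording.flow[np.where(m)[0][-1]]
        ok = ok and (abs(last_exp_flow) > zero_flow_tol)
    return bool(ok)
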