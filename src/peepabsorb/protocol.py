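"""The full pre/post measurement protocol for one simulated patient.

Sequence (mirroring the bedside study): stabilize at ZEEP; triplicate
end-inspiratory and end-expiratory 4-s occlusions with at least ten
uninterrupted breaths between maneuvers; triplicate abdominal-compression
maneuvers for flow-limitation testing; apply PEEP equal to 80 % of the
measured auto-PEEP (rounded to integer cmH2O); stabilize; repeat the
occlusions.  Patients with auto-PEEP below the enrollment threshold are
flagged ineligible rather than raising.
"""
from __future__ import annotations

import numpy as np

from .absorber import (
    StudyMeasurements,
    applied_peep_from_autopeep,
    classify_absorber,
)
from .config import DetectorConfig, ProtocolConfig, SolverConfig
from .errors import IneligiblePatientError
from .flowlimit import build_loop, classify_patient_fl, detect_flow_limitation
from .mechanics import (
    check_persistent_expiratory_flow,
    compute_mechanics,
    measure_peak_pressure,
    measure_plateau,
    validate_triplicate,
)
from .simulator import (
    _finalize,
    _render_breath,
    advance_breaths,
    expire_once,
    occlusion_end_volumes,
    simulate_compression,
    simulate_occlusion,
    steady_state_volumes,
)
from .ventilation import Interval, LungModel, VentilatorSettings

__all__ = ["run_protocol", "measure_phase"]


def _render_one_breath(model, settings, volumes, fs, rng, noise_sd):
    arrays, v_ei, v_ee = _render_breath(model, settings, volumes, 0.0, fs)
    tcyc = settings.cycle_time
    rec = _finalize([arrays], [Interval("breath", 0.0, tcyc)], fs, rng, noise_sd)
    return rec, v_ei, v_ee


def measure_phase(model: LungModel, settings: VentilatorSettings,
                  protocol: ProtocolConfig, solver: SolverConfig,
                  rng: np.random.Generator, store_waveforms: bool = False):
    """Triplicate occlusion measurements for one PEEP phase.

    Returns (mechanics MechanicsMeasurement, segments dict).
    """
    fs = solver.sample_rate
    reps = protocol.repetitions
    v = steady_state_volumes(model, settings, "end_exp")
    ppk, pplat, peeptot = [], [], []
    segments: dict[str, list] = {"breath": [], "occl_insp": [], "occl_exp": []}
    for _ in range(reps):
        v = advance_breaths(model, settings, v, protocol.breaths_between - 1)
        breath, v_ei, v_ee = _render_one_breath(
            model, settings, v, fs, rng, model.noise_sd)
        ppk.append(measure_peak_pressure(breath))
        occ_i = simulate_occlusion(
            model, settings, v_ei, "end_inspiratory",
            duration=protocol.occlusion_duration, sample_rate=fs,
            seed=int(rng.integers(2**31)),
            collateral_resistance=solver.collateral_resistance,
            plateau_slope_tol=solver.plateau_slope_tol)
        pplat.append(measure_plateau(occ_i, solver.plateau_window,
                                     solver.zero_flow_tol,
                                     solver.plateau_slope_tol))
        v = occlusion_end_volumes(model, v_ei, protocol.occlusion_duration,
                                  solver.collateral_resistance)
        # finish the interrupted cycle passively, then recover
        v = expire_once(model, settings, v)
        v = advance_breaths(model, settings, v, protocol.breaths_between)
        occ_e = simulate_occlusion(
            model, settings, v, "end_expiratory",
            duration=protocol.occlusion_duration, sample_rate=fs,
            seed=int(rng.integers(2**31)),
            collateral_resistance=solver.collateral_resistance,
            plateau_slope_tol=solver.plateau_slope_tol)
        peeptot.append(measure_plateau(occ_e, solver.plateau_window,
                                       solver.zero_flow_tol,
                                       solver.plateau_slope_tol))
        v = occlusion_end_volumes(model, v, protocol.occlusion_duration,
                                  solver.collateral_resistance)
        v = advance_breaths(model, settings, v, protocol.breaths_between)
        if store_waveforms:
            segments["breath"].append(breath)
            segments["occl_insp"].append(occ_i)
            segments["occl_exp"].append(occ_e)
    valid = (validate_triplicate(ppk) and validate_triplicate(pplat)
             and validate_triplicate(peeptot))
    mech = compute_mechanics(
        ppk=float(np.mean(ppk)), pplat=float(np.mean(pplat)),
        peep_tot=float(np.mean(peeptot)), applied_peep=settings.applied_peep,
        tidal_volume=settings.tidal_volume,
        inspiratory_flow=settings.inspiratory_flow, valid=valid,
        triplicates={"ppk": ppk, "pplat": pplat, "peep_tot": peeptot})
    return mech, segments


def _flow_limitation_assessment(model, settings, protocol, solver, detector,
                                rng, store_waveforms):
    fs = solver.sample_rate
    verdicts, fractions = [], []
    loops = []
    v = steady_state_volumes(model, settings, "end_insp")
    for m in range(protocol.repetitions):
        passive, compressed = simulate_compression(
            model, settings, v, protocol.compression_delta,
            seed=int(rng.integers(2**31)), sample_rate=fs)
        lp = build_loop(passive, detector.grid_points, maneuver_id=m)
        lc = build_loop(compressed, detector.grid_points, maneuver_id=m)
        fl, frac = detect_flow_limitation(
            lp, lc, tol_abs=detector.tol_abs, tol_rel=detector.tol_rel,
            min_fraction=detector.min_fraction,
            grid_points=detector.grid_points)
        verdicts.append(fl)
        fractions.append(frac)
        if store_waveforms:
            loops.append((passive, compressed))
    return classify_patient_fl(verdicts), tuple(fractions), loops


def run_protocol(model: LungModel, settings: VentilatorSettings,
                 protocol: ProtocolConfig | None = None,
                 solver: SolverConfig | None = None,
                 detector: DetectorConfig | None = None,
                 seed: int = 0,
                 store_waveforms: bool = False) -> StudyMeasurements:
    """Execute the full study protocol on one patient model.

    The returned StudyMeasurements carries both phases, the bedside
    flow-limitation verdict and (via ``classify_absorber``) the label.
    An auto-PEEP below the enrollment threshold flags the patient
    ineligible; the PEEP phase is then skipped.
    """
    protocol = protocol or ProtocolConfig()
    solver = solver or SolverConfig()
    detector = detector or DetectorConfig()
    rng = np.random.default_rng(seed)
    fs = solver.sample_rate
    zeep = settings.with_peep(0.0)

    # screening breaths: persistence of expiratory flow before inspiration
    from .simulator import simulate_breaths
    v0 = steady_state_volumes(model, zeep, "end_exp")
    screen = simulate_breaths(model, zeep, 3, sample_rate=fs,
                              seed=int(rng.integers(2**31)),
                              initial_volumes=v0)
    persistent = check_persistent_expiratory_flow(screen, solver.zero_flow_tol)

    mech_zeep, seg_zeep = measure_phase(model, zeep, protocol, solver, rng,
                                        store_waveforms)
    fl, fractions, loops = _flow_limitation_assessment(
        model, zeep, protocol, solver, detector, rng, store_waveforms)

    waveforms = {}
    if store_waveforms:
        waveforms["zeep"] = seg_zeep
        waveforms["screen"] = screen
        waveforms["loops"] = loops

    try:
        applied = applied_peep_from_autopeep(
            mech_zeep.auto_peep, fraction=protocol.peep_fraction,
            enrollment_threshold=protocol.enrollment_threshold)
    except IneligiblePatientError:
        return StudyMeasurements(
            zeep=mech_zeep, peep_phase=None, applied_peep=0.0, fl=fl,
            eligible=False, persistent_expiratory_flow=persistent,
            superimposed_fractions=fractions, waveforms=waveforms)

    peep_settings = settings.with_peep(float(applied))
    mech_peep, seg_peep = measure_phase(model, peep_settings, protocol, solver,
                                        rng, store_waveforms)
    if store_waveforms:
        waveforms["peep"] = seg_peep
    return StudyMeasurements(
        zeep=mech_zeep, peep_phase=mech_peep, applied_peep=float(applied),
        fl=fl, eligible=True, persistent_expiratory_flow=persistent,
        superimposed_fractions=fractions, waveforms=waveforms)


def label_patient(measurements: StudyMeasurements):
    """Convenience: classify the absorber behaviour of a completed protocol."""
    return classify_absorber(measurements)
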