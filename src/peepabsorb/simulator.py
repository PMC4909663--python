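"""Mechanistic simulation of passive volume-controlled ventilation.

The lung is one or more parallel RC compartments.  Inspiration delivers a
constant flow split across compartments by ``volume_share``.  Expiration of a
non-flow-limited compartment is Ohmic, ``q = (Palv - Pao) / R_exp``; a
flow-limited compartment expires at the lesser of the Ohmic flow and a
maximal-flow envelope ``q_max = k * V`` (volume above relaxation volume), so
that on the envelope the flow does not depend on airway-opening pressure.
During an airway occlusion the compartments equilibrate through the common
airway plus a fixed collateral pathway, and the occluded plateau converges to
the compliance-weighted mean alveolar pressure.

All phase dynamics are linear, so every segment is integrated exactly
(piecewise exponentials); the sampling grid only affects what is recorded,
never the state trajectory.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import (
    CalibrationError,
    InvalidModelError,
    StepSizeError,
)
from .ventilation import (
    Compartment,
    Interval,
    LungModel,
    VentilatorSettings,
    WaveformRecording,
    concatenate,
)

__all__ = [
    "simulate_breaths",
    "simulate_occlusion",
    "simulate_compression",
    "calibrate_two_compartment_patient",
    "steady_state_volumes",
    "steady_state_autopeep",
    "occluded_total_peep",
    "closed_form_autopeep",
]


# ---------------------------------------------------------------------------
# exact expiration of a single compartment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Segment:
    kind: str          # "ohmic" | "envelope" | "stuck"
    t_start: float     # s from expiration onset
    v_start: float     # L above relaxation volume
    duration: float    # s, may be inf


def _plan_expiration(comp: Compartment, v0: float, peep: float,
                     delta: float) -> list[_Segment]:
    """Piecewise plan of one expiration: at most one regime switch.

    ``delta`` is the extra alveolar pressure from abdominal compression.
    """
    tau = comp.tau_exp
    vinf = comp.compliance * (peep - delta)   # Ohmic attractor
    if not comp.flow_limited:
        return [_Segment("ohmic", 0.0, v0, math.inf)]

    k = comp.envelope_slope
    a = 1.0 - k * tau
    if v0 <= 0.0 and vinf < v0:
        # envelope flow is zero at/below relaxation volume: no expiratory flow
        return [_Segment("stuck", 0.0, v0, math.inf)]
    if v0 < vinf:
        # re-inflation from the circuit; the envelope never limits inflow
        return [_Segment("ohmic", 0.0, v0, math.inf)]

    if a > 0.0:
        if vinf <= 0.0:
            return [_Segment("envelope", 0.0, v0, math.inf)]
        vstar = vinf / a
        if v0 > vstar:
            t1 = math.log(v0 / vstar) / k
            return [_Segment("envelope", 0.0, v0, t1),
                    _Segment("ohmic", t1, vstar, math.inf)]
        return [_Segment("ohmic", 0.0, v0, math.inf)]
    # a <= 0: Ohmic is the lesser flow except at low volumes under compression
    if vinf >= 0.0:
        return [_Segment("ohmic", 0.0, v0, math.inf)]
    vb = vinf / a   # > 0
    if v0 > vb:
        t1 = tau * math.log((v0 - vinf) / (vb - vinf))
        return [_Segment("ohmic", 0.0, v0, t1),
                _Segment("envelope", t1, vb, math.inf)]
    return [_Segment("envelope", 0.0, v0, math.inf)]


def _segment_eval(comp: Compartment, seg: _Segment, peep: float, delta: float,
                  t: np.ndarray | float):
    """Volume and expiratory flow within one segment at local time t."""
    tau = comp.tau_exp
    vinf = comp.compliance * (peep - delta)
    if seg.kind == "ohmic":
        v = vinf + (seg.v_start - vinf) * np.exp(-np.asarray(t) / tau)
        q = (v - vinf) / tau
    elif seg.kind == "envelope":
        v = seg.v_start * np.exp(-comp.envelope_slope * np.asarray(t))
        q = comp.envelope_slope * v
    else:  # stuck
        v = np.full_like(np.asarray(t, dtype=float), seg.v_start)
        q = np.zeros_like(v)
    return v, q


def _expire(comp: Compartment, v0: float, duration: float, peep: float,
            delta: float = 0.0, ts: np.ndarray | None = None):
    """Integrate one expiration exactly.

    Returns ``(v_end, v_samples, q_samples)``; the sample arrays are None
    when ``ts`` is None.  ``ts`` are times from expiration onset.
    """
    plan = _plan_expiration(comp, v0, peep, delta)
    v_s = q_s = None
    if ts is not None:
        v_s = np.empty_like(ts)
        q_s = np.empty_like(ts)
    v_end = v0
    for i, seg in enumerate(plan):
        seg_end = seg.t_start + seg.duration
        if ts is not None:
            lo = seg.t_start - 1e-12
            hi = min(seg_end, duration)
            m = (ts >= lo) & (ts < hi) if i < len(plan) - 1 else (ts >= lo)
            if m.any():
                v_s[m], q_s[m] = _segment_eval(comp, seg, peep, delta,
                                               ts[m] - seg.t_start)
        if duration <= seg_end:
            v_end, _ = _segment_eval(comp, seg, peep, delta,
                                     duration - seg.t_start)
            v_end = float(v_end)
            break
    return v_end, v_s, q_s


def _expire_end(comp: Compartment, v0: float, duration: float, peep: float,
                delta: float = 0.0) -> float:
    return _expire(comp, v0, duration, peep, delta)[0]


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def closed_form_autopeep(tidal_volume: float, compliance: float,
                         expiratory_time: float, rate_constant: float) -> float:
    """Steady-state auto-PEEP of one compartment emptying mono-exponentially.

    ``rate_constant`` is ``1/(R_exp C)`` for Ohmic emptying or the envelope
    slope ``k`` for a fully flow-limited expiration:
    ``auto-PEEP = (VT/C) / (exp(rate * Te) - 1)``.
    """
    return (tidal_volume / compliance) / math.expm1(rate_constant * expiratory_time)


def _steady_end_exp_volume(comp: Compartment, settings: VentilatorSettings) -> float:
    """End-expiratory volume above relaxation volume at steady state."""
    te = settings.expiratory_time
    vt_i = comp.volume_share * settings.tidal_volume
    peep = settings.applied_peep
    if not comp.flow_limited:
        # exact: V_ee - C*PEEP follows the ZEEP recursion
        ratio = te / comp.tau_exp
        if ratio > 500.0:       # complete exhalation within one cycle
            return comp.compliance * peep
        return comp.compliance * peep + vt_i / math.expm1(ratio)
    k = comp.envelope_slope
    if peep == 0.0 and k * comp.tau_exp < 1.0:
        if k * te > 500.0:
            return 0.0
        return vt_i / math.expm1(k * te)

    def f(v):
        return _expire_end(comp, v + vt_i, te, peep) - v

    vhi = comp.compliance * (peep + 400.0) + vt_i
    return brentq(f, 0.0, vhi, xtol=1e-12)


def steady_state_volumes(model: LungModel, settings: VentilatorSettings,
                         at: str = "end_exp") -> np.ndarray:
    """Per-compartment steady-state volumes at end-expiration or end-inspiration."""
    v = np.array([_steady_end_exp_volume(c, settings) for c in model.compartments])
    if at == "end_insp":
        v = v + np.array([c.volume_share for c in model.compartments]) \
            * settings.tidal_volume
    elif at != "end_exp":
        raise ValueError("at must be 'end_exp' or 'end_insp'")
    return v


def occluded_total_peep(model: LungModel, settings: VentilatorSettings) -> float:
    """Analytic end-expiratory occlusion plateau: compliance-weighted mean
    alveolar pressure, equal to total trapped volume over total compliance."""
    v = steady_state_volumes(model, settings, "end_exp")
    return float(v.sum() / model.total_compliance)


def steady_state_autopeep(model: LungModel, settings: VentilatorSettings) -> float:
    """Occluded total PEEP minus applied PEEP at steady state."""
    return occluded_total_peep(model, settings) - settings.applied_peep


def expire_once(model: LungModel, settings: VentilatorSettings,
                volumes: np.ndarray) -> np.ndarray:
    """Passive expiration over Te from the given (end-inspiratory) state."""
    te = settings.expiratory_time
    return np.array([
        _expire_end(c, float(v), te, settings.applied_peep)
        for c, v in zip(model.compartments, np.asarray(volumes, dtype=float))
    ])


def advance_breaths(model: LungModel, settings: VentilatorSettings,
                    volumes: np.ndarray, n_breaths: int) -> np.ndarray:
    """Propagate compartment volumes through n un-rendered breaths."""
    v = np.asarray(volumes, dtype=float).copy()
    te = settings.expiratory_time
    for _ in range(n_breaths):
        for i, c in enumerate(model.compartments):
            v[i] = _expire_end(c, v[i] + c.volume_share * settings.tidal_volume,
                               te, settings.applied_peep)
    return v


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _grid(t0: float, duration: float, fs: float) -> np.ndarray:
    i0 = int(math.ceil(t0 * fs - 1e-9))
    i1 = int(math.ceil((t0 + duration) * fs - 1e-9))
    return np.arange(i0, i1) / fs


def _check_step(model: LungModel, fs: float) -> None:
    tau_min = model.min_time_constant()
    if 1.0 / fs > tau_min:
        raise StepSizeError(
            f"sample interval {1.0 / fs:.4f} s exceeds the smallest "
            f"compartment time constant {tau_min:.4f} s; raise sample_rate"
        )


def _render_breath(model: LungModel, settings: VentilatorSettings,
                   volumes: np.ndarray, t0: float, fs: float):
    """Render one breath; returns (arrays dict, v_end_insp, v_end_exp)."""
    ti, te = settings.inspiratory_time, settings.expiratory_time
    vdot = settings.inspiratory_flow
    shares = np.array([c.volume_share for c in model.compartments])
    comps = model.compartments

    ts_in = _grid(t0, ti, fs)
    rel_in = ts_in - t0
    paw_in = np.zeros_like(rel_in)
    for c, s, v0 in zip(comps, shares, volumes):
        v_t = v0 + s * vdot * rel_in
        paw_in += s * (v_t / c.compliance + c.resistance * s * vdot)
    flow_in = np.full_like(rel_in, vdot)
    v_ei = volumes + shares * settings.tidal_volume
    vol_in = (volumes.sum() + vdot * rel_in) - volumes.sum()

    ts_ex = _grid(t0 + ti, te, fs)
    rel_ex = ts_ex - (t0 + ti)
    q_tot = np.zeros_like(rel_ex)
    v_tot = np.zeros_like(rel_ex)
    v_ee = np.empty_like(volumes)
    for i, c in enumerate(comps):
        v_end, v_s, q_s = _expire(c, v_ei[i], te, settings.applied_peep, 0.0,
                                  ts=rel_ex)
        v_ee[i] = v_end
        q_tot += q_s
        v_tot += v_s
    paw_ex = np.full_like(rel_ex, settings.applied_peep)
    flow_ex = -q_tot
    vol_ex = v_tot - volumes.sum()

    arrays = {
        "time": np.concatenate([ts_in, ts_ex]),
        "paw": np.concatenate([paw_in, paw_ex]),
        "flow": np.concatenate([flow_in, flow_ex]),
        "volume": np.concatenate([vol_in, vol_ex]),
        "phase": np.array(["insp"] * len(ts_in) + ["exp"] * len(ts_ex),
                          dtype=object),
    }
    return arrays, v_ei, v_ee


def _finalize(parts: list[dict], annotations: list[Interval], fs: float,
              rng: np.random.Generator | None, noise_sd: float,
              flow_noise_sd: float = 0.0) -> WaveformRecording:
    time = np.concatenate([p["time"] for p in parts])
    paw = np.concatenate([p["paw"] for p in parts])
    flow = np.concatenate([p["flow"] for p in parts])
    vol = np.concatenate([p["volume"] for p in parts])
    phase = np.concatenate([p["phase"] for p in parts])
    if rng is not None and noise_sd > 0:
        paw = paw + rng.normal(0.0, noise_sd, size=paw.shape)
    if rng is not None and flow_noise_sd > 0:
        flow = flow + rng.normal(0.0, flow_noise_sd, size=flow.shape)
    t0 = time[0]
    return WaveformRecording(
        sample_rate=fs,
        time=time - t0,
        airway_pressure=paw,
        flow=flow,
        volume=vol,
        phase=phase,
        annotations=[Interval(a.label, a.start - t0, a.end - t0)
                     for a in annotations],
    )


def simulate_breaths(model: LungModel, settings: VentilatorSettings,
                     n_breaths: int, sample_rate: float = 100.0,
                     seed: int = 0, initial_volumes: np.ndarray | None = None,
                     ) -> WaveformRecording:
    """Simulate ``n_breaths`` ventilator cycles from ``initial_volumes``
    (default: relaxation volume, i.e. the first breaths build up auto-PEEP).

    Gaussian noise of sd ``model.noise_sd`` is added to the pressure trace;
    the simulation is deterministic given ``seed``.
    """
    if n_breaths < 1:
        raise InvalidModelError("n_breaths must be >= 1")
    _check_step(model, sample_rate)
    rng = np.random.default_rng(seed)
    v = (np.zeros(model.n_compartments) if initial_volumes is None
         else np.asarray(initial_volumes, dtype=float).copy())
    parts, anns = [], []
    tcyc = settings.cycle_time
    for b in range(n_breaths):
        t0 = b * tcyc
        arrays, _, v = _render_breath(model, settings, v, t0, sample_rate)
        parts.append(arrays)
        anns.append(Interval("breath", t0, t0 + tcyc))
    return _finalize(parts, anns, sample_rate, rng, model.noise_sd)


# ---------------------------------------------------------------------------
# occlusion
# ---------------------------------------------------------------------------

def _occlusion_system(model: LungModel, collateral_resistance: float):
    """Linear redistribution system dV/dt = A V during an occlusion."""
    comps = model.compartments
    g = np.array([1.0 / c.resistance + 1.0 / collateral_resistance
                  for c in comps])
    cvec = np.array([c.compliance for c in comps])
    gtot = g.sum()
    n = len(comps)
    a_mat = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a_mat[i, j] = g[i] * g[j] / (cvec[j] * gtot)
        a_mat[i, i] -= g[i] / cvec[i]
    return a_mat, g, cvec, gtot


def _occlusion_volumes(model: LungModel, volumes: np.ndarray,
                       collateral_resistance: float, ts: np.ndarray):
    """Exact volumes V(ts) and node pressure during occlusion."""
    a_mat, g, cvec, gtot = _occlusion_system(model, collateral_resistance)
    if model.n_compartments == 1:
        v_t = np.tile(volumes, (len(ts), 1))
    else:
        lam, s_mat = np.linalg.eig(a_mat)
        coef = np.linalg.solve(s_mat, volumes)
        v_t = np.real((s_mat @ (coef[:, None]
                                * np.exp(np.outer(lam, ts)))).T)
    palv = v_t / cvec
    p_node = (palv * g).sum(axis=1) / gtot
    return v_t, p_node


def simulate_occlusion(model: LungModel, settings: VentilatorSettings,
                       volumes: np.ndarray, kind: str, duration: float = 4.0,
                       sample_rate: float = 100.0, seed: int = 0,
                       collateral_resistance: float = 25.0,
                       plateau_slope_tol: float = 0.05) -> WaveformRecording:
    """Clamp airway flow to zero from the given compartment state.

    ``kind`` is ``"end_inspiratory"`` or ``"end_expiratory"``.  The airway
    pressure trace converges to the compliance-weighted mean alveolar
    pressure; if |dP/dt| at the end of the maneuver still exceeds
    ``plateau_slope_tol`` a ``plateau_warning`` annotation is attached.
    """
    if duration <= 0:
        raise InvalidModelError("occlusion duration must be positive")
    if kind not in ("end_inspiratory", "end_expiratory"):
        raise ValueError("kind must be end_inspiratory or end_expiratory")
    _check_step(model, sample_rate)
    rng = np.random.default_rng(seed)
    volumes = np.asarray(volumes, dtype=float)
    ts = _grid(0.0, duration, sample_rate)
    v_t, p_node = _occlusion_volumes(model, volumes, collateral_resistance, ts)
    label = "occl_insp" if kind == "end_inspiratory" else "occl_exp"
    anns = [Interval(label, 0.0, duration)]
    if len(ts) >= 2:
        slope_end = abs(p_node[-1] - p_node[-2]) * sample_rate
        if slope_end > plateau_slope_tol:
            anns.append(Interval("plateau_warning", 0.0, duration))
    part = {
        "time": ts,
        "paw": p_node,
        "flow": np.zeros_like(ts),
        "volume": v_t.sum(axis=1) - volumes.sum(),
        "phase": np.array([label] * len(ts), dtype=object),
    }
    return _finalize([part], anns, sample_rate, rng, model.noise_sd)


def occlusion_end_volumes(model: LungModel, volumes: np.ndarray,
                          duration: float,
                          collateral_resistance: float = 25.0) -> np.ndarray:
    """Compartment volumes at the end of an occlusion (for protocol chaining)."""
    v_t, _ = _occlusion_volumes(model, np.asarray(volumes, dtype=float),
                                collateral_resistance, np.array([duration]))
    return v_t[0]


# ---------------------------------------------------------------------------
# abdominal compression
# ---------------------------------------------------------------------------

def simulate_compression(model: LungModel, settings: VentilatorSettings,
                         volumes_end_insp: np.ndarray, delta_pressure: float,
                         seed: int = 0, sample_rate: float = 100.0,
                         ) -> tuple[WaveformRecording, WaveformRecording]:
    """Paired passive and compressed expirations from the same end-inspiratory
    state.

    Compression adds ``delta_pressure`` to every compartment's alveolar
    pressure for the whole expiration, beginning as soon as insufflation ends.
    A compartment on its flow envelope is unaffected wherever the envelope
    binds.  Returns ``(passive, compressed)`` expiration segments.
    """
    if delta_pressure <= 0:
        raise InvalidModelError("delta_pressure must be positive")
    _check_step(model, sample_rate)
    rng = np.random.default_rng(seed)
    v_ei = np.asarray(volumes_end_insp, dtype=float)
    te = settings.expiratory_time
    ts = _grid(0.0, te, sample_rate)
    segs = []
    for delta, label in ((0.0, "exp"), (delta_pressure, "compression")):
        q_tot = np.zeros_like(ts)
        v_tot = np.zeros_like(ts)
        for i, c in enumerate(model.compartments):
            _, v_s, q_s = _expire(c, v_ei[i], te, settings.applied_peep,
                                  delta, ts=ts)
            q_tot += q_s
            v_tot += v_s
        part = {
            "time": ts,
            "paw": np.full_like(ts, settings.applied_peep),
            "flow": -q_tot,
            "volume": v_tot - v_ei.sum(),
            "phase": np.array([label] * len(ts), dtype=object),
        }
        segs.append(_finalize([part], [Interval(label, 0.0, te)], sample_rate,
                              rng, model.noise_sd))
    return segs[0], segs[1]


def compressed_end_volumes(model: LungModel, settings: VentilatorSettings,
                           volumes_end_insp: np.ndarray,
                           delta_pressure: float) -> np.ndarray:
    v_ei = np.asarray(volumes_end_insp, dtype=float)
    te = settings.expiratory_time
    return np.array([
        _expire_end(c, v_ei[i], te, settings.applied_peep, delta_pressure)
        for i, c in enumerate(model.compartments)
    ])


# ---------------------------------------------------------------------------
# worked-example two-compartment calibration
# ---------------------------------------------------------------------------

def _calibrate_nonfl_resistance(target: float, compliance: float, share: float,
                                settings: VentilatorSettings) -> float:
    vt_i = share * settings.tidal_volume
    te = settings.expiratory_time

    def f(r):
        comp = Compartment(resistance=r, compliance=compliance,
                           volume_share=share)
        return _steady_end_exp_volume(comp, settings.with_peep(0.0)) \
            / compliance - target

    lo, hi = 1e-2, 2000.0
    if f(hi) < 0:
        raise CalibrationError(
            f"non-FL auto-PEEP target {target} unreachable", residual=f(hi))
    return brentq(f, lo, hi, xtol=1e-10)


def _calibrate_envelope_slope(target: float, compliance: float, share: float,
                              resistance: float,
                              settings: VentilatorSettings) -> float:
    def f(k):
        comp = Compartment(resistance=resistance, compliance=compliance,
                           volume_share=share, flow_limited=True,
                           envelope_slope=k)
        return _steady_end_exp_volume(comp, settings.with_peep(0.0)) \
            / compliance - target

    lo, hi = 1e-4, 50.0
    f_lo, f_hi = f(lo), f(hi)
    if f_lo < 0 or f_hi > 0:
        residual = f_lo if f_lo < 0 else f_hi
        raise CalibrationError(
            f"FL auto-PEEP target {target} unreachable with R={resistance} "
            "(Ohmic pathway empties faster than any binding envelope)",
            residual=residual)
    return brentq(f, lo, hi, xtol=1e-10)


def calibrate_two_compartment_patient(target_autopeep_nfl: float,
                           target_autopeep_fl: float,
                           settings: VentilatorSettings,
                           total_compliance: float = 1.0 / 19.0,
                           fl_resistance: float = 20.0,
                           noise_sd: float = 0.2,
                           tol: float = 0.1) -> LungModel:
    """Two-compartment model with equal volume shares whose compartmental
    steady-state auto-PEEPs at ZEEP match the targets.

    The non-flow-limited compartment is calibrated by root-finding over its
    resistance, the flow-limited one over its envelope slope (Ohmic resistance
    fixed at ``fl_resistance``).  Raises CalibrationError (with the residual)
    if a target is unreachable.
    """
    if target_autopeep_nfl <= 0 or target_autopeep_fl <= 0:
        raise CalibrationError("targets must be positive")
    c_i = total_compliance / 2.0
    r_nfl = _calibrate_nonfl_resistance(target_autopeep_nfl, c_i, 0.5, settings)
    k_fl = _calibrate_envelope_slope(target_autopeep_fl, c_i, 0.5,
                                     fl_resistance, settings)
    model = LungModel(compartments=(
        Compartment(resistance=r_nfl, compliance=c_i, volume_share=0.5),
        Compartment(resistance=fl_resistance, compliance=c_i, volume_share=0.5,
                    flow_limited=True, envelope_slope=k_fl),
    ), noise_sd=noise_sd)
    zeep = settings.with_peep(0.0)
    achieved = steady_state_volumes(model, zeep, "end_exp") / c_i
    resid = np.abs(achieved - np.array([target_autopeep_nfl, target_autopeep_fl]))
    if resid.max() > tol:
        raise CalibrationError("calibration residual too large",
                               residual=float(resid.max()))
    return model
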