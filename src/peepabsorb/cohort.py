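"""Synthetic study cohort: lung models, ventilator prescriptions, covariates.

The generator emulates the published cohort's structure.  Each patient is
drawn as one of four mechanistic phenotypes:

``complete``
    All-flow-limited lung with near-homogeneous compartmental auto-PEEPs,
    all above the PEEP that will be applied: total PEEP does not rise.
``high``
    All-flow-limited but heterogeneous: the low-auto-PEEP compartment is
    re-inflated up to the applied PEEP while the high one is shielded by its
    envelope, so total PEEP rises by less than half the applied PEEP.
``low_fl``
    Severely heterogeneous flow-limited lung (a large, nearly open region
    plus a small region with very high trapped pressure): most of the lung
    takes up the applied PEEP.
``low_nonfl``
    Purely Ohmic lung: applied PEEP is transmitted in full.

Phenotype probabilities default to 0.33 / 0.21 / 0.07 / 0.39, making 61 % of
patients flow limited, and covariates are drawn class-conditionally so their
marginals approximate the published per-class characteristics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .absorber import classify_absorber
from .config import CohortConfig, DetectorConfig, ProtocolConfig, SolverConfig
from .errors import ConfigError
from .protocol import run_protocol
from .ventilation import Compartment, LungModel, VentilatorSettings

__all__ = ["SyntheticPatient", "generate_cohort", "run_study"]

_TYPES = ("complete", "high", "low_fl", "low_nonfl")


@dataclass
class SyntheticPatient:
    patient_id: int
    model: LungModel
    settings: VentilatorSettings
    covariates: dict = field(default_factory=dict)
    phenotype: str = "low_nonfl"

    @property
    def flow_limited(self) -> bool:
        """Generating ground-truth flag."""
        return self.model.flow_limited


def _tnorm(rng, mean, sd, lo, hi) -> float:
    if not (lo < hi) or sd <= 0:
        raise ConfigError(f"invalid distribution (mean={mean}, sd={sd}, "
                          f"bounds=({lo}, {hi}))")
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _envelope_slope(vt_i: float, c_i: float, autopeep: float, te: float) -> float:
    """Envelope slope giving the target steady-state auto-PEEP when the whole
    expiration rides the envelope at ZEEP."""
    return math.log1p(vt_i / (c_i * autopeep)) / te


def _predicted_applied(total_autopeep: float, fraction: float = 0.8) -> int:
    return int(math.floor(fraction * total_autopeep + 0.5))


def _fl_compartment(share: float, c_tot: float, r_insp_tot: float,
                    autopeep: float, vt: float, te: float,
                    r_exp: float) -> Compartment:
    c_i = share * c_tot
    k = _envelope_slope(share * vt, c_i, autopeep, te)
    return Compartment(resistance=r_insp_tot / share, compliance=c_i,
                       volume_share=share, flow_limited=True,
                       envelope_slope=k, expiratory_resistance=r_exp)


def _shielding_r_exp(share: float, c_tot: float, autopeep: float, vt: float,
                     te: float, applied: float, safety: float = 0.5) -> float:
    """Expiratory Ohmic resistance small enough that the envelope still binds
    at end-expiration under the applied PEEP (k * R_exp * C < 1 - P/aP)."""
    c_i = share * c_tot
    k = _envelope_slope(share * vt, c_i, autopeep, te)
    margin = max(1.0 - applied / autopeep, 0.02)
    return max(safety * margin / (k * c_i), 1.0)


def _make_model(rng, phenotype: str, cfg: CohortConfig,
                settings: VentilatorSettings, noise_sd: float) -> LungModel:
    te = settings.expiratory_time
    vt = settings.tidal_volume
    e_tot = _tnorm(rng, *cfg.elastance, *cfg.elastance_bounds)
    c_tot = 1.0 / e_tot
    r_tot = _tnorm(rng, *cfg.resistance, *cfg.resistance_bounds)

    if phenotype == "low_nonfl":
        total = _tnorm(rng, *cfg.autopeep_low, *cfg.autopeep_bounds)
        # expiratory time constant required for the target trapped pressure
        tau_exp = te / math.log1p(vt / (c_tot * total))
        comp = Compartment(resistance=r_tot, compliance=c_tot,
                           volume_share=1.0,
                           expiratory_resistance=tau_exp / c_tot)
        return LungModel((comp,), noise_sd=noise_sd)

    if phenotype == "complete":
        total = _tnorm(rng, *cfg.autopeep_complete, *cfg.autopeep_bounds)
        spread = rng.uniform(*cfg.complete_spread)
        ap = (total * (1 - spread), total * (1 + spread))
        applied = _predicted_applied(total)
        comps = tuple(
            _fl_compartment(0.5, c_tot, r_tot, ap_i, vt, te,
                            _shielding_r_exp(0.5, c_tot, ap_i, vt, te, applied))
            for ap_i in ap)
        return LungModel(comps, noise_sd=noise_sd)

    if phenotype == "high":
        total = _tnorm(rng, *cfg.autopeep_high, *cfg.autopeep_bounds)
        applied = _predicted_applied(total)
        lo_frac = max(cfg.high_delta_frac[0], 1.15 / applied)
        frac = rng.uniform(lo_frac, cfg.high_delta_frac[1])
        ap1 = applied * (1.0 - 2.0 * frac)      # re-inflated compartment
        ap2 = 2.0 * total - ap1                 # shielded compartment
        c1 = 0.5 * c_tot
        comp1 = _fl_compartment(0.5, c_tot, r_tot, ap1, vt, te,
                                r_exp=max(te / (8.0 * c1), 1.0))
        comp2 = _fl_compartment(0.5, c_tot, r_tot, ap2, vt, te,
                                _shielding_r_exp(0.5, c_tot, ap2, vt, te,
                                                 applied))
        return LungModel((comp1, comp2), noise_sd=noise_sd)

    if phenotype == "low_fl":
        total = _tnorm(rng, cfg.autopeep_low[0], cfg.autopeep_low[1],
                       cfg.autopeep_bounds[0], 6.8)
        applied = _predicted_applied(total)
        w = cfg.low_fl_share
        frac = rng.uniform(*cfg.low_fl_delta_frac)
        ap1 = max(applied * (1.0 - frac / w), 0.4)
        ap2 = (total - w * ap1) / (1.0 - w)
        c1 = w * c_tot
        comp1 = _fl_compartment(w, c_tot, r_tot, ap1, vt, te,
                                r_exp=max(te / (8.0 * c1), 1.0))
        comp2 = _fl_compartment(1.0 - w, c_tot, r_tot, ap2, vt, te,
                                _shielding_r_exp(1.0 - w, c_tot, ap2, vt, te,
                                                 applied))
        return LungModel((comp1, comp2), noise_sd=noise_sd)

    raise ConfigError(f"unknown phenotype {phenotype!r}")


def _draw_covariates(rng, cls_idx: int, cfg: CohortConfig) -> dict:
    return {
        "age": _tnorm(rng, *cfg.age[cls_idx], 18.0, 100.0),
        "female": bool(rng.random() < cfg.female[cls_idx]),
        "bmi": _tnorm(rng, *cfg.bmi[cls_idx], 15.0, 55.0),
        "chronic_pulmonary_disease":
            bool(rng.random() < cfg.chronic_pulmonary_disease[cls_idx]),
        "acute_pulmonary_disease":
            bool(rng.random() < cfg.acute_pulmonary_disease[cls_idx]),
        "smoking_history": bool(rng.random() < cfg.smoking_history[cls_idx]),
        "pao2_fio2": _tnorm(rng, *cfg.pao2_fio2[cls_idx], 60.0, 600.0),
        "supine": bool(rng.random() < cfg.supine[cls_idx]),
    }


def generate_cohort(n: int, config: CohortConfig | None = None,
                    seed: int = 0,
                    noise_sd: float = 0.2) -> list[SyntheticPatient]:
    """Draw ``n`` reproducible synthetic patients (sub-seeded by counter)."""
    if n < 1:
        raise ConfigError("cohort size n must be >= 1")
    cfg = config or CohortConfig()
    probs = np.array([cfg.p_complete, cfg.p_high, cfg.p_low_fl,
                      cfg.p_low_nonfl])
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigError("phenotype probabilities p_* must be a distribution")
    patients = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        phenotype = _TYPES[rng.choice(4, p=probs)]
        cls_idx = {"complete": 0, "high": 1, "low_fl": 2, "low_nonfl": 2}[phenotype]
        rr_params = (cfg.rr_complete, cfg.rr_high, cfg.rr_low)[cls_idx]
        rr = round(_tnorm(rng, *rr_params, *cfg.rr_bounds))
        ti = _tnorm(rng, *cfg.inspiratory_time, 0.7, 1.3)
        # guarantee a workable expiratory time
        while 60.0 / rr - ti < 0.5:
            rr -= 1
        vt_per_ibw = _tnorm(rng, *cfg.vt_per_ibw, 5.0, 12.0)
        ibw = _tnorm(rng, *cfg.ibw, 40.0, 90.0)
        vt = float(np.clip(vt_per_ibw * ibw / 1000.0, 0.30, 0.85))
        settings = VentilatorSettings(tidal_volume=vt, respiratory_rate=rr,
                                      inspiratory_time=ti, applied_peep=0.0)
        model = _make_model(rng, phenotype, cfg, settings, noise_sd)
        cov = _draw_covariates(rng, cls_idx, cfg)
        cov["tidal_volume_per_ibw"] = vt_per_ibw
        patients.append(SyntheticPatient(
            patient_id=i, model=model, settings=settings,
            covariates=cov, phenotype=phenotype))
    return patients


def run_study(patients: list[SyntheticPatient],
              protocol: ProtocolConfig | None = None,
              solver: SolverConfig | None = None,
              detector: DetectorConfig | None = None,
              seed: int = 0) -> tuple[pd.DataFrame, list]:
    """Run the full measurement protocol on every patient.

    Returns the analysis cohort table (one row per patient; mechanics are the
    *measured* values) and the list of StudyMeasurements.
    """
    rows, results = [], []
    for p in patients:
        m = run_protocol(p.model, p.settings, protocol=protocol,
                         solver=solver, detector=detector,
                         seed=int(np.random.default_rng([seed, 7919, p.patient_id])
                                  .integers(2**31)))
        results.append(m)
        row = {
            "patient_id": p.patient_id,
            "respiratory_rate": p.settings.respiratory_rate,
            "expiratory_time": p.settings.expiratory_time,
            "minute_ventilation": p.settings.minute_ventilation,
            **p.covariates,
            "flow_limited": m.fl,
            "flow_limited_true": p.flow_limited,
            "phenotype": p.phenotype,
            "eligible": m.eligible,
            "valid": m.valid,
            "persistent_expiratory_flow": m.persistent_expiratory_flow,
            "total_peep_zeep": m.zeep.peep_tot,
            "auto_peep_zeep": m.zeep.auto_peep,
            "resistance": m.zeep.resistance,
            "elastance": m.zeep.elastance,
            "applied_peep": m.applied_peep,
        }
        if m.eligible and m.peep_phase is not None:
            row["total_peep_peep"] = m.peep_phase.peep_tot
            row["delta_peep_tot"] = m.delta_peep_tot
            row["delta_pct_of_applied"] = m.delta_percent_of_applied
            row["label"] = str(classify_absorber(m))
        else:
            row["total_peep_peep"] = np.nan
            row["delta_peep_tot"] = np.nan
            row["delta_pct_of_applied"] = np.nan
            row["label"] = None
        rows.append(row)
    return pd.DataFrame(rows), results
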