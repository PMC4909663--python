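"""Run configuration: solver, protocol, detector, cohort and analysis options.

Every field has a default; a serialized config plus the seed reproduces a run
exactly.  Configs are plain dataclasses, YAML round-trippable.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError


@dataclass
class SolverConfig:
    """Waveform rendering and numerical tolerances."""

    sample_rate: float = 100.0          # Hz
    noise_sd: float = 0.2               # cmH2O, additive Gaussian on pressure
    flow_noise_sd: float = 0.0          # L/s, off by default
    zero_flow_tol: float = 0.02         # L/s, occlusion integrity / end-exp flow
    plateau_slope_tol: float = 0.05     # cmH2O/s
    plateau_window: float = 0.5         # s, averaging window at occlusion end
    collateral_resistance: float = 25.0  # cmH2O.s/L inter-compartment path during occlusion
    steady_state_tol: float = 1e-8      # L, fixed-point tolerance


@dataclass
class ProtocolConfig:
    """The pre/post measurement protocol."""

    occlusion_duration: float = 4.0     # s
    repetitions: int = 3                # triplicate maneuvers
    breaths_between: int = 10           # uninterrupted breaths between maneuvers
    peep_fraction: float = 0.8          # applied PEEP = fraction of auto-PEEP at ZEEP
    enrollment_threshold: float = 5.0   # cmH2O auto-PEEP at ZEEP
    compression_delta: float = 10.0     # cmH2O added to alveolar pressure during MCA


@dataclass
class DetectorConfig:
    """Flow-volume loop superposition tolerances."""

    tol_abs: float = 0.02               # L/s
    tol_rel: float = 0.05               # fraction of passive flow
    min_fraction: float = 0.20          # contiguous superimposed share of overlap
    grid_points: int = 200


@dataclass
class AnalysisConfig:
    """Statistical pipeline options."""

    folds: int = 10
    bootstrap_reps: int = 2000
    alpha: float = 0.05
    vif_threshold: float = 5.0
    calibration_smoother: str = "lowess"   # or "bins"
    calibration_bins: int = 10
    auroc_pooling: str = "pooled"          # or "per_fold"
    penalized_fallback: bool = False       # L2 fallback on separation
    refit_threshold_in_cv: bool = True


@dataclass
class CohortConfig:
    """Distribution parameters of the synthetic cohort.

    Class-conditional parameters emulate the published cohort's marginals:
    intended absorber-behaviour types with probabilities summing to 1, a
    flow-limitation prevalence of 61 %, respiratory rates of roughly 16, 20 and
    22 /min in the complete/high/low classes, elastance around 19 cmH2O/L and
    inspiratory resistance around 18-21 cmH2O.s/L.
    """

    # intended-behaviour type probabilities (complete/high are flow limited by
    # construction; "low_fl" is the severely heterogeneous flow-limited low
    # absorber, "low_nonfl" the purely Ohmic one).  0.33+0.21+0.07 = 61 % FL.
    p_complete: float = 0.33
    p_high: float = 0.21
    p_low_fl: float = 0.07
    p_low_nonfl: float = 0.39

    # respiratory rate, breaths/min (mean, sd), truncated and rounded:
    # complete absorbers breathe slowly; all other patients share one
    # distribution
    rr_complete: tuple[float, float] = (16.0, 3.0)
    rr_high: tuple[float, float] = (22.0, 4.0)
    rr_low: tuple[float, float] = (22.0, 4.0)
    rr_bounds: tuple[float, float] = (8.0, 32.0)

    inspiratory_time: tuple[float, float] = (1.0, 0.1)   # s (mean, sd)
    vt_per_ibw: tuple[float, float] = (8.0, 1.0)         # mL/kg IBW
    ibw: tuple[float, float] = (62.0, 9.0)               # kg
    elastance: tuple[float, float] = (19.0, 5.0)         # cmH2O/L
    elastance_bounds: tuple[float, float] = (9.0, 38.0)
    resistance: tuple[float, float] = (19.5, 5.0)        # cmH2O.s/L, inspiratory
    resistance_bounds: tuple[float, float] = (8.0, 40.0)

    # total auto-PEEP target at ZEEP per class, cmH2O
    autopeep_complete: tuple[float, float] = (8.0, 2.5)
    autopeep_high: tuple[float, float] = (8.0, 2.5)
    autopeep_low: tuple[float, float] = (5.6, 1.0)
    autopeep_bounds: tuple[float, float] = (5.2, 16.0)

    # compartmental heterogeneity
    complete_spread: tuple[float, float] = (0.0, 0.10)   # |aP_i - T|/T, uniform
    high_delta_frac: tuple[float, float] = (0.22, 0.45)  # target dPEEPtot / applied
    low_fl_delta_frac: tuple[float, float] = (0.55, 0.70)
    low_fl_share: float = 0.8            # volume share of the low-auto-PEEP compartment

    # covariates, class-conditional (complete, high, low)
    age: tuple = ((74.0, 8.0), (71.0, 10.0), (69.0, 12.0))
    female: tuple = (0.55, 0.24, 0.41)
    bmi: tuple = ((30.0, 7.0), (31.0, 7.0), (26.0, 5.0))
    chronic_pulmonary_disease: tuple = (0.76, 0.57, 0.22)
    acute_pulmonary_disease: tuple = (0.84, 0.57, 0.28)
    smoking_history: tuple = (0.75, 0.45, 0.34)
    pao2_fio2: tuple = ((203.0, 82.0), (205.0, 89.0), (306.0, 137.0))
    supine: tuple = (0.64, 0.48, 0.46)


@dataclass
class RunConfig:
    """Top-level configuration; aggregates all option groups plus the seed."""

    seed: int = 42
    cohort_size: int = 100
    solver: SolverConfig = field(default_factory=SolverConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def validate(self) -> "RunConfig":
        if self.cohort_size < 1:
            raise ConfigError("cohort_size must be >= 1")
        if self.solver.sample_rate <= 0:
            raise ConfigError("solver.sample_rate must be positive")
        if not 0 < self.protocol.peep_fraction <= 1:
            raise ConfigError("protocol.peep_fraction must be in (0, 1]")
        c = self.cohort
        total = c.p_complete + c.p_high + c.p_low_fl + c.p_low_nonfl
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("cohort type probabilities p_* must sum to 1")
        if self.analysis.folds < 2:
            raise ConfigError("analysis.folds must be >= 2")
        return self


def _to_dict(cfg: Any) -> Any:
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        return {f.name: _to_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}
    if isinstance(cfg, tuple):
        return list(cfg)
    return cfg


def _from_dict(cls, data: dict) -> Any:
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "solver", "protocol", "detector", "analysis", "cohort"
        ):
            sub = {"solver": SolverConfig, "protocol": ProtocolConfig,
                   "detector": DetectorConfig, "analysis": AnalysisConfig,
                   "cohort": CohortConfig}[f.name]
            value = _from_dict(sub, value)
        elif isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[f.name] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # unknown field
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML; missing fields keep their defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(RunConfig, data).validate()


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)
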