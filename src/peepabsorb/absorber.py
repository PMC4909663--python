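"""PEEP-absorber study definitions and pre/post classification.

After measuring auto-PEEP at ZEEP, external PEEP equal to 80 % of it is
applied and total PEEP re-measured.  A patient is a *complete* PEEP-absorber
when total PEEP increases by at most 1 cmH2O (the stated accuracy of the
pressure measurement; decreases also count), a *high* absorber when the
increase is below 50 % of the applied PEEP, and a *low* absorber otherwise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IneligiblePatientError, UndefinedPercentageError
from .mechanics import MechanicsMeasurement

__all__ = [
    "StudyMeasurements",
    "AbsorberLabel",
    "LABELS",
    "applied_peep_from_autopeep",
    "classify_absorber",
    "summarize_cohort",
]

LABELS = ("complete", "high", "low")

COMPLETE_DELTA_MAX = 1.0       # cmH2O, inclusive
HIGH_FRACTION_MAX = 0.5        # strict: delta < 50 % of applied PEEP


@dataclass(frozen=True)
class AbsorberLabel:
    label: str

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")

    def __str__(self) -> str:
        return self.label


@dataclass
class StudyMeasurements:
    """Everything the pre/post protocol measures for one patient."""

    zeep: MechanicsMeasurement
    peep_phase: MechanicsMeasurement | None
    applied_peep: float
    fl: bool | None = None                      # bedside flow-limitation verdict
    eligible: bool = True                       # auto-PEEP >= threshold at ZEEP
    persistent_expiratory_flow: bool | None = None
    superimposed_fractions: tuple = field(default_factory=tuple)
    waveforms: dict = field(default_factory=dict)

    @property
    def delta_peep_tot(self) -> float | None:
        if self.peep_phase is None:
            return None
        return self.peep_phase.peep_tot - self.zeep.peep_tot

    @property
    def delta_percent_of_applied(self) -> float | None:
        if self.peep_phase is None:
            return None
        if self.applied_peep <= 0:
            raise UndefinedPercentageError("applied PEEP must be positive")
        return 100.0 * self.delta_peep_tot / self.applied_peep

    @property
    def valid(self) -> bool:
        ok = self.zeep.valid
        if self.peep_phase is not None:
            ok = ok and self.peep_phase.valid
        return ok


def applied_peep_from_autopeep(auto_peep_zeep: float,
                               fraction: float = 0.8,
                               enrollment_threshold: float = 5.0) -> int:
    """External PEEP prescription: ``fraction`` of auto-PEEP at ZEEP, rounded
    to the nearest settable integer cmH2O (ties up)."""
    if auto_peep_zeep < enrollment_threshold:
        raise IneligiblePatientError(
            f"auto-PEEP {auto_peep_zeep:.2f} cmH2O below enrollment "
            f"threshold {enrollment_threshold} cmH2O"
        )
    return int(math.floor(fraction * auto_peep_zeep + 0.5))


def classify_absorber(measurements: StudyMeasurements) -> AbsorberLabel:
    """Label the pre/post response: complete / high / low PEEP-absorber."""
    delta = measurements.delta_peep_tot
    if delta is None:
        raise ValueError("PEEP-phase measurements missing")
    if measurements.applied_peep <= 0:
        raise UndefinedPercentageError("applied PEEP must be positive")
    if delta <= COMPLETE_DELTA_MAX:
        return AbsorberLabel("complete")
    if delta < HIGH_FRACTION_MAX * measurements.applied_peep:
        return AbsorberLabel("high")
    return AbsorberLabel("low")


def summarize_cohort(labels, measurements) -> dict:
    """Cohort-level summary: class fractions, delta-PEEPtot histogram data
    (absolute and as % of applied PEEP) and per-class descriptive statistics.
    """
    labels = [str(l) for l in labels]
    measurements = list(measurements)
    if len(labels) != len(measurements) or not labels:
        raise ValueError("need one measurement per label, non-empty")
    n = len(labels)
    counts = {lab: labels.count(lab) for lab in LABELS}
    fractions = {lab: counts[lab] / n for lab in LABELS}
    deltas = np.array([m.delta_peep_tot for m in measurements], dtype=float)
    pct = np.array([m.delta_percent_of_applied for m in measurements],
                   dtype=float)
    rows = []
    for lab, m in zip(labels, measurements):
        rows.append({
            "label": lab,
            "auto_peep_zeep": m.zeep.auto_peep,
            "applied_peep": m.applied_peep,
            "peep_tot_zeep": m.zeep.peep_tot,
            "peep_tot_peep": m.peep_phase.peep_tot,
            "delta": m.delta_peep_tot,
            "delta_pct": m.delta_percent_of_applied,
            "elastance": m.zeep.elastance,
            "resistance": m.zeep.resistance,
            "fl": m.fl,
        })
    frame = pd.DataFrame(rows)
    per_class = {}
    for lab in LABELS:
        sub = frame[frame["label"] == lab]
        stats = {}
        for col in ("auto_peep_zeep", "applied_peep", "peep_tot_zeep",
                    "peep_tot_peep", "delta", "delta_pct", "elastance",
                    "resistance"):
            if len(sub):
                stats[col] = (float(sub[col].mean()), float(sub[col].std(ddof=1))
                              if len(sub) > 1 else 0.0)
            else:
                stats[col] = (float("nan"), float("nan"))
        stats["n"] = int(len(sub))
        per_class[lab] = stats
    hist_abs = np.histogram(deltas, bins=np.arange(-2.5, 8.0, 1.0))
    hist_pct = np.histogram(pct, bins=np.arange(-50.0, 151.0, 12.5))
    return {
        "n": n,
        "counts": counts,
        "fractions": fractions,
        "delta_cmh2o": deltas,
        "delta_pct_of_applied": pct,
        "hist_delta_cmh2o": hist_abs,
        "hist_delta_pct": hist_pct,
        "per_class": per_class,
        "frame": frame,
    }
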