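"""Domain types: ventilator prescription, compartmental lung model, waveforms.

Conventions
-----------
* Pressures in cmH2O, volumes in L, flows in L/s, times in s.
* Compartment volume ``V`` is measured above the compartment's relaxation
  volume at zero airway pressure, so elastic recoil is ``V / C``.
* Airway-opening flow is inspiratory-positive.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidModelError, InvalidSettingsError

__all__ = [
    "VentilatorSettings",
    "Compartment",
    "LungModel",
    "Interval",
    "WaveformRecording",
]


@dataclass(frozen=True)
class VentilatorSettings:
    """Volume-controlled, constant-flow ventilation prescription.

    Parameters
    ----------
    tidal_volume : float
        Tidal volume VT in L.
    respiratory_rate : float
        Set rate RR in breaths/min.
    inspiratory_time : float
        Ti in s.  Inspiratory flow is constant, ``VT / Ti``.
    applied_peep : float
        External PEEP in cmH2O (0 = ZEEP).
    """

    tidal_volume: float
    respiratory_rate: float
    inspiratory_time: float
    applied_peep: float = 0.0

    def __post_init__(self):
        if self.tidal_volume <= 0:
            raise InvalidSettingsError("tidal_volume must be positive")
        if self.respiratory_rate <= 0:
            raise InvalidSettingsError("respiratory_rate must be positive")
        if self.inspiratory_time <= 0:
            raise InvalidSettingsError("inspiratory_time must be positive")
        if self.applied_peep < 0:
            raise InvalidSettingsError("applied_peep must be >= 0")
        if self.expiratory_time <= 0:
            raise InvalidSettingsError(
                f"expiratory time 60/RR - Ti = {self.expiratory_time:.3f} s "
                "must be positive"
            )

    @property
    def cycle_time(self) -> float:
        return 60.0 / self.respiratory_rate

    @property
    def expiratory_time(self) -> float:
        return self.cycle_time - self.inspiratory_time

    @property
    def inspiratory_flow(self) -> float:
        """Constant inspiratory flow in L/s."""
        return self.tidal_volume / self.inspiratory_time

    @property
    def minute_ventilation(self) -> float:
        """VT x RR in L/min."""
        return self.tidal_volume * self.respiratory_rate

    def with_peep(self, peep: float) -> "VentilatorSettings":
        """Same prescription with a different applied PEEP."""
        return replace(self, applied_peep=peep)


@dataclass(frozen=True)
class Compartment:
    """One RC region of the lung, optionally expiratory-flow limited.

    A flow-limited compartment expires at the lesser of the Ohmic flow
    ``(Palv - Pao) / R_exp`` and the maximal-flow envelope ``k * V`` where
    ``k = envelope_slope`` and ``V`` the volume above relaxation volume.  On
    the envelope, expiratory flow is independent of airway-opening pressure.

    ``expiratory_resistance`` defaults to ``resistance``; it exists because
    the Ohmic pathway relevant during expiration (and hence the volume at
    which the envelope stops binding) need not equal the inspiratory
    resistance measured from Ppk - Pplat.
    """

    resistance: float                 # cmH2O.s/L, inspiratory Ohmic
    compliance: float                 # L/cmH2O
    volume_share: float = 1.0         # fraction of each tidal breath
    flow_limited: bool = False
    envelope_slope: float | None = None        # (L/s)/L, only when flow_limited
    expiratory_resistance: float | None = None  # cmH2O.s/L, defaults to resistance

    def __post_init__(self):
        if self.resistance <= 0:
            raise InvalidModelError("resistance must be positive")
        if self.compliance <= 0:
            raise InvalidModelError("compliance must be positive")
        if not 0 < self.volume_share <= 1:
            raise InvalidModelError("volume_share must be in (0, 1]")
        if self.flow_limited:
            if self.envelope_slope is None or self.envelope_slope <= 0:
                raise InvalidModelError(
                    "flow_limited compartment requires envelope_slope > 0"
                )
        elif self.envelope_slope is not None:
            raise InvalidModelError(
                "envelope_slope only meaningful when flow_limited"
            )
        if self.expiratory_resistance is not None and self.expiratory_resistance <= 0:
            raise InvalidModelError("expiratory_resistance must be positive")

    @property
    def r_exp(self) -> float:
        return (self.expiratory_resistance
                if self.expiratory_resistance is not None else self.resistance)

    @property
    def elastance(self) -> float:
        return 1.0 / self.compliance

    @property
    def tau_exp(self) -> float:
        """Expiratory Ohmic time constant R_exp * C in s."""
        return self.r_exp * self.compliance


@dataclass(frozen=True)
class LungModel:
    """Parallel collection of compartments plus sensor-noise level."""

    compartments: tuple[Compartment, ...]
    noise_sd: float = 0.2             # cmH2O on airway pressure samples

    def __post_init__(self):
        if len(self.compartments) < 1:
            raise InvalidModelError("at least one compartment required")
        shares = sum(c.volume_share for c in self.compartments)
        if abs(shares - 1.0) > 1e-6:
            raise InvalidModelError(
                f"volume_share values must sum to 1 (got {shares:.6f})"
            )
        if self.noise_sd < 0:
            raise InvalidModelError("noise_sd must be >= 0")

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    @property
    def total_compliance(self) -> float:
        return sum(c.compliance for c in self.compartments)

    @property
    def total_elastance(self) -> float:
        return 1.0 / self.total_compliance

    @property
    def inspiratory_resistance(self) -> float:
        """Series-equivalent resistance seen at the airway opening during a
        volume-share-split constant-flow inflation: sum s_i^2 R_i."""
        return sum(c.volume_share**2 * c.resistance for c in self.compartments)

    @property
    def flow_limited(self) -> bool:
        """True when any compartment carries a flow-limitation envelope."""
        return any(c.flow_limited for c in self.compartments)

    def min_time_constant(self) -> float:
        taus = []
        for c in self.compartments:
            taus.append(c.tau_exp)
            if c.flow_limited:
                taus.append(1.0 / c.envelope_slope)
        return min(taus)


@dataclass(frozen=True)
class Interval:
    """Labelled time interval within a recording."""

    label: str        # breath | occl_insp | occl_exp | exp | compression | ...
    start: float      # s, inclusive
    end: float        # s, exclusive

    def mask(self, time: np.ndarray) -> np.ndarray:
        return (time >= self.start - 1e-12) & (time < self.end - 1e-12)


@dataclass
class WaveformRecording:
    """Uniformly sampled airway pressure / flow / volume traces.

    ``volume`` is the running integral of flow re-zeroed at each breath's
    start of inspiration.  ``phase`` labels every sample with one of
    ``insp, exp, occl_insp, occl_exp, compression``.
    """

    sample_rate: float
    time: np.ndarray
    airway_pressure: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    phase: np.ndarray                      # dtype=object array of str
    annotations: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.time)
        for name in ("airway_pressure", "flow", "volume", "phase"):
            if len(getattr(self, name)) != n:
                raise InvalidModelError(f"{name} length mismatch with time axis")
        if n >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-9):
                raise InvalidModelError("time axis must be uniform at 1/sample_rate")

    @property
    def duration(self) -> float:
        return len(self.time) / self.sample_rate

    def segment(self, interval: Interval) -> "WaveformRecording":
        """Extract the samples of one annotated interval (time re-zeroed)."""
        m = interval.mask(self.time)
        sub = [a for a in self.annotations
               if a.start >= interval.start - 1e-9 and a.end <= interval.end + 1e-9
               and a is not interval]
        t0 = self.time[m][0] if m.any() else 0.0
        return WaveformRecording(
            sample_rate=self.sample_rate,
            time=self.time[m] - t0,
            airway_pressure=self.airway_pressure[m],
            flow=self.flow[m],
            volume=self.volume[m],
            phase=self.phase[m],
            annotations=[Interval(a.label, a.start - t0, a.end - t0) for a in sub],
        )

    def intervals(self, label: str) -> list[Interval]:
        return [a for a in self.annotations if a.label == label]


def concatenate(parts: list[WaveformRecording]) -> WaveformRecording:
    """Stitch consecutive recording parts onto one continuous time axis."""
    if not parts:
        raise InvalidModelError("nothing to concatenate")
    fs = parts[0].sample_rate
    out_t, out_p, out_f, out_v, out_ph = [], [], [], [], []
    anns: list[Interval] = []
    offset = 0.0
    for part in parts:
        if part.sample_rate != fs:
            raise InvalidModelError("sample_rate mismatch in concatenation")
        out_t.append(part.time + offset)
        out_p.append(part.airway_pressure)
        out_f.append(part.flow)
        out_v.append(part.volume)
        out_ph.append(part.phase)
        anns.extend(Interval(a.label, a.start + offset, a.end + offset)
                    for a in part.annotations)
        offset += len(part.time) / fs
    return WaveformRecording(
        sample_rate=fs,
        time=np.concatenate(out_t),
        airway_pressure=np.concatenate(out_p),
        flow=np.concatenate(out_f),
        volume=np.concatenate(out_v),
        phase=np.concatenate(out_ph),
        annotations=anns,
    )
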