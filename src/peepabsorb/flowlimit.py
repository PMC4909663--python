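"""Expiratory flow-limitation detection by flow-volume loop superposition.

The bedside maneuver compares a passive expiration with one performed under
manual compression of the abdomen.  If raising alveolar pressure does not
raise expiratory flow over some volume range, that range is flow limited.
The visual criterion is operationalized as: a grid point is superimposed when
``|flow_c - flow_p| <= max(tol_abs, tol_rel * flow_p)``, and the maneuver is
positive when a contiguous superimposed run covers at least ``min_fraction``
of the overlapping expired-volume range.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .config import DetectorConfig
from .errors import ManeuverRejectedError, UndeterminableError
from .ventilation import WaveformRecording

__all__ = [
    "FlowVolumeLoop",
    "build_loop",
    "detect_flow_limitation",
    "classify_patient_fl",
]


@dataclass
class FlowVolumeLoop:
    """Expiratory flow magnitude on a uniform expired-volume grid."""

    expired_volume: np.ndarray    # L, monotone from 0 to total expired volume
    expiratory_flow: np.ndarray   # L/s, magnitude
    maneuver_id: int = 0

    @property
    def total_volume(self) -> float:
        return float(self.expired_volume[-1])


def build_loop(segment: WaveformRecording, grid_points: int = 200,
               maneuver_id: int = 0,
               monotone_tol: float = 0.02) -> FlowVolumeLoop:
    """Resample an expiration onto a uniform expired-volume grid.

    Expired volume is the running integral of expiratory flow magnitude;
    a cumulative volume that back-tracks by more than ``monotone_tol`` of the
    total (inspiratory flow inside the segment) rejects the maneuver.
    """
    if len(segment.time) < 4:
        raise ManeuverRejectedError("expiration segment too short")
    flow = -segment.flow          # expiratory flow positive
    expired = cumulative_trapezoid(flow, segment.time, initial=0.0)
    total = expired[-1]
    if total <= 1e-3:
        raise ManeuverRejectedError("no expired volume in segment")
    running_max = np.maximum.accumulate(expired)
    if np.max(running_max - expired) > monotone_tol * total:
        raise ManeuverRejectedError(
            "cumulative expired volume non-monotone beyond tolerance"
        )
    grid = np.linspace(0.0, total, grid_points)
    # use the monotone running maximum as the interpolation axis
    flow_on_grid = np.interp(grid, running_max, np.maximum(flow, 0.0))
    return FlowVolumeLoop(expired_volume=grid, expiratory_flow=flow_on_grid,
                          maneuver_id=maneuver_id)


def detect_flow_limitation(passive: FlowVolumeLoop, compressed: FlowVolumeLoop,
                           tol_abs: float = 0.02, tol_rel: float = 0.05,
                           min_fraction: float = 0.20,
                           grid_points: int = 200) -> tuple[bool, float]:
    """Superimpose the two loops over their common expired-volume range.

    Returns ``(flow_limited, superimposed_fraction)`` where the fraction is
    the longest contiguous superimposed run as a share of the overlap range.
    """
    overlap = min(passive.total_volume, compressed.total_volume)
    if overlap <= 1e-6:
        raise UndeterminableError("loops share no expired-volume overlap")
    grid = np.linspace(0.0, overlap, grid_points)
    fp = np.interp(grid, passive.expired_volume, passive.expiratory_flow)
    fc = np.interp(grid, compressed.expired_volume, compressed.expiratory_flow)
    tol = np.maximum(tol_abs, tol_rel * fp)
    superimposed = np.abs(fc - fp) <= tol
    frac = _longest_run(superimposed) / len(grid)
    return bool(frac >= min_fraction), float(frac)


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for flag in mask:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best


def classify_patient_fl(results) -> bool:
    """Flow limited only when all three maneuvers are positive."""
    results = list(results)
    if len(results) != 3:
        raise ValueError("exactly three maneuver outcomes required")
    return all(bool(r) for r in results)


def detector_from_config(cfg: DetectorConfig):
    """Bind detect_flow_limitation to a DetectorConfig."""
    def detect(passive, compressed):
        return detect_flow_limitation(
            passive, compressed, tol_abs=cfg.tol_abs, tol_rel=cfg.tol_rel,
            min_fraction=cfg.min_fraction, grid_points=cfg.grid_points)
    return detect
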