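"""CSV interfaces: waveform recordings and cohort tables.

Waveform CSV layout: columns ``time_s, paw_cmh2o, flow_lps, volume_l, phase``
with ``phase`` one of ``insp, exp, occl_insp, occl_exp, compression``; one
file per patient-phase, UTF-8, mandatory header row.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .ventilation import Interval, WaveformRecording

WAVEFORM_COLUMNS = ["time_s", "paw_cmh2o", "flow_lps", "volume_l", "phase"]
PHASES = {"insp", "exp", "occl_insp", "occl_exp", "compression"}

COHORT_COLUMNS = [
    "patient_id", "age", "female", "bmi", "respiratory_rate",
    "expiratory_time", "minute_ventilation", "tidal_volume_per_ibw",
    "resistance", "elastance", "flow_limited", "chronic_pulmonary_disease",
    "acute_pulmonary_disease", "smoking_history", "pao2_fio2", "supine",
    "total_peep_zeep", "applied_peep", "label",
]


def waveform_to_frame(rec: WaveformRecording) -> pd.DataFrame:
    return pd.DataFrame({
        "time_s": rec.time,
        "paw_cmh2o": rec.airway_pressure,
        "flow_lps": rec.flow,
        "volume_l": rec.volume,
        "phase": rec.phase.astype(str),
    })


def write_waveform_csv(rec: WaveformRecording, path: str | Path) -> None:
    waveform_to_frame(rec).to_csv(path, index=False)


def read_waveform_csv(path: str | Path) -> WaveformRecording:
    df = pd.read_csv(path)
    missing = [c for c in WAVEFORM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"waveform CSV missing columns: {missing}")
    bad = set(df["phase"].astype(str).unique()) - PHASES
    if bad:
        raise SchemaError(f"unknown phase values: {sorted(bad)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError("waveform CSV needs at least two samples")
    dt = np.diff(t)
    if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-4):
        raise SchemaError("time_s must be strictly increasing and uniform")
    phase = df["phase"].astype(str).to_numpy(dtype=object)
    # reconstruct contiguous phase intervals as annotations
    anns = []
    start = 0
    for i in range(1, len(phase) + 1):
        if i == len(phase) or phase[i] != phase[start]:
            anns.append(Interval(str(phase[start]), float(t[start]),
                                 float(t[i - 1] + dt[0])))
            start = i
    return WaveformRecording(
        sample_rate=1.0 / float(dt[0]),
        time=t,
        airway_pressure=df["paw_cmh2o"].to_numpy(dtype=float),
        flow=df["flow_lps"].to_numpy(dtype=float),
        volume=df["volume_l"].to_numpy(dtype=float),
        phase=phase,
        annotations=anns,
    )


def write_cohort_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV missing columns: {missing}")
    bad = df.index[df["respiratory_rate"] <= 0].tolist()
    if bad:
        raise SchemaError(f"rows {bad}: respiratory_rate must be positive")
    if "label" in df.columns:
        known = df["label"].dropna().isin(["complete", "high", "low"])
        if not known.all():
            rows = df["label"].dropna()[~known].index.tolist()
            raise SchemaError(f"rows {rows}: unknown absorber label")
    return df


def write_mechanics_csv(rows: list[dict], path: str | Path) -> None:
    cols = ["patient_id", "phase", "ppk", "pplat", "peep_tot", "applied_peep",
            "auto_peep", "compliance", "elastance", "resistance", "valid"]
    pd.DataFrame(rows)[cols].to_csv(path, index=False)
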