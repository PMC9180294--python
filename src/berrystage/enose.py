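"""E-nose feature extraction.

A measurement is an 80 s trace per sensor of the conductance ratio G/G0
(sensor conductance under sample gas over conductance under clean gas).
The feature submitted to statistics is the mean response in the 70–75 s
window, where the MOS sensors have reached their plateau.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .reference import SENSOR_NAMES

#: Feature window in seconds, both endpoints inclusive.
DEFAULT_WINDOW: tuple[float, float] = (70.0, 75.0)

META_COLUMNS = ("stage", "harvest", "sample_id", "replicate")


@dataclass
class SensorTrace:
    """One sensor's conductance-ratio time series for one measurement."""

    sensor_id: str
    time: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape or self.time.ndim != 1:
            raise ValueError("time and value must be 1-D arrays of equal length")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.value)) or np.any(self.value <= 0):
            raise ValueError("trace values must be finite and positive")


def relative_conductance(
    time: np.ndarray, raw: np.ndarray, baseline: float, sensor_id: str = "S1"
) -> SensorTrace:
    """Convert a raw conductance series to the G/G0 ratio trace.

    Parameters
    ----------
    time, raw : arrays
        Acquisition grid (s) and raw conductance values.
    baseline : float
        Clean-gas conductance G0; must be positive.
    """
    if not np.isfinite(baseline) or baseline <= 0:
        raise ValueError("baseline conductance must be positive and finite")
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw conductance values must be finite")
    return SensorTrace(sensor_id=sensor_id, time=np.asarray(time, float), value=raw / baseline)


def window_feature(trace: SensorTrace, window: tuple[float, float] = DEFAULT_WINDOW) -> float:
    """Mean response over the plateau window (endpoints inclusive).

    On the 1 Hz grid this equals the trapezoidal area under the curve
    divided by the window length to within 0.1%; the window mean is the
    convention implemented.
    """
    t_start, t_end = window
    if t_start >= t_end:
        raise ValueError("window must satisfy t_start < t_end")
    if t_start < trace.time[0] or t_end > trace.time[-1]:
        raise ValueError("feature window lies outside the trace support")
    inside = (trace.time >= t_start) & (trace.time <= t_end)
    if int(inside.sum()) < 2:
        raise ValueError("fewer than 2 grid points inside the feature window")
    return float(trace.value[inside].mean())


def assemble_feature_table(
    observations: Iterable[Mapping],
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Build the observations x sensors feature table.

    ``observations`` is an iterable of mappings (or objects with the same
    attributes) carrying ``stage``, ``harvest``, ``sample_id``,
    ``replicate`` and ``traces`` — a dict sensor id -> :class:`SensorTrace`
    covering all 10 sensors.  Returns one row per (sample, replicate) with
    metadata columns followed by S1..S10 window-mean features.
    """
    rows = []
    seen: set[tuple[str, int]] = set()
    for obs in observations:
        get = obs.get if isinstance(obs, Mapping) else lambda k, o=obs: getattr(o, k)
        traces = get("traces")
        missing = [s for s in SENSOR_NAMES if s not in traces]
        if missing:
            raise ValueError(f"observation is missing sensors: {missing}")
        key = (get("sample_id"), get("replicate"))
        if key in seen:
            raise ValueError(f"duplicate observation for (sample, replicate) {key}")
        seen.add(key)
        row = {
            "stage": get("stage"),
            "harvest": get("harvest"),
            "sample_id": get("sample_id"),
            "replicate": get("replicate"),
        }
        for s in SENSOR_NAMES:
            row[s] = window_feature(traces[s], window)
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(SENSOR_NAMES))
    if table[list(SENSOR_NAMES)].isna().any().any():
        raise ValueError("feature table contains missing cells")
    return table


def read_trace_csv(path: str | Path) -> dict[str, SensorTrace]:
    """Read one observation's trace CSV (columns: time_s, S1..S10)."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: trace CSV must have a time_s column")
    time = df["time_s"].to_numpy(float)
    return {
        s: SensorTrace(sensor_id=s, time=time, value=df[s].to_numpy(float))
        for s in SENSOR_NAMES
        if s in df.columns
    }


def write_trace_csv(path: str | Path, traces: Mapping[str, SensorTrace]) -> None:
    first = next(iter(traces.values()))
    out = pd.DataFrame({"time_s": first.time})
    for s in SENSOR_NAMES:
        out[s] = traces[s].value
    out.to_csv(path, index=False)
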