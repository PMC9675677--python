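"""Sensor traces and wave summary statistics.

The simulator records the model fields at a small set of probe locations
("sensors").  This module reduces those traces to the headline quantities of
a spark/wave experiment: per-sensor cytosolic peaks, SR troughs, normalised
fluorescence, blink amplitude, wave speed and termination time, plus paired
comparisons between runs (e.g. buffered versus buffer-free).

Fluorescence conventions: the model's only fluorescent species is the
Ca2+-bound dye, so F/F0 = [CaF](t) / [CaF](rest) and dF/F0 = F/F0 - 1.  The
blink amplitude is the magnitude of the minimum of the SR dF/F0 trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .params import ModelParams

__all__ = ["SensorTraces", "WaveSummary", "summarize", "compare_runs"]


@dataclass
class SensorTraces:
    """Time series of the model fields at the probe locations.

    ``data`` maps a variable name ("C", "C_S", "CaF", "CaF_SR") to an array
    of shape (n_times, n_sensors).  ``sensor_x`` holds the longitudinal
    probe coordinates in um (``sensor_y`` the transverse one for 2-D runs).
    """

    times: np.ndarray
    data: Dict[str, np.ndarray]
    sensor_x: np.ndarray
    sensor_y: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, arr in self.data.items():
            if arr.shape[0] != len(self.times):
                raise ValueError(f"series {name!r} length does not match times")

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_x)


@dataclass
class WaveSummary:
    """Per-sensor and aggregate wave statistics (concentrations in uM)."""

    sensor_x: np.ndarray
    c_rest: float
    cs_rest: float
    peak_c: np.ndarray                      # per-sensor max cytosolic Ca2+
    trough_cs: np.ndarray                   # per-sensor min SR Ca2+
    f_f0_peak_per_sensor: Optional[np.ndarray] = None
    f_f0_peak: Optional[float] = None       # max over sensors
    blink_per_sensor: Optional[np.ndarray] = None
    blink_amplitude: Optional[float] = None  # |min dF/F0| in the SR
    wave_speed: Optional[float] = None       # um/s, from arrival-time regression
    termination_time: Optional[float] = None  # ms

    @property
    def depletion(self) -> np.ndarray:
        """Per-sensor SR depletion, rest minus trough (uM)."""
        return self.cs_rest - self.trough_cs


def _arrival_time(t: np.ndarray, y: np.ndarray, baseline: float) -> Optional[float]:
    """First crossing of half the peak excursion, linearly interpolated."""
    peak = y.max()
    if peak <= baseline:
        return None
    thr = baseline + 0.5 * (peak - baseline)
    above = y >= thr
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    return float(t0 + (thr - y0) / (y1 - y0) * (t1 - t0))


def summarize(traces: SensorTraces, params: ModelParams,
              source_x: Optional[float] = None) -> WaveSummary:
    """Reduce sensor traces to a :class:`WaveSummary`.

    ``source_x`` is the wave-initiation coordinate used for the speed
    regression (defaults to the sensor farthest-right position's midpoint
    convention: the maximum sensor coordinate).  Wave speed comes from a
    least-squares fit of distance-from-source against half-peak arrival
    time; a flat trace contributes no arrival and fewer than two arrivals
    yield no speed (None, not zero).
    """
    if len(traces.times) == 0:
        raise ValueError("empty traces")
    t = traces.times
    C = traces.data["C"]
    CS = traces.data["C_S"]
    peak_c = C.max(axis=0)
    trough_cs = CS.min(axis=0)

    f_f0_sensor = f_f0_peak = None
    if "CaF" in traces.data:
        caf = traces.data["CaF"]
        f0 = caf[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(f0 > 0, caf / f0, np.nan)
        f_f0_sensor = np.nanmax(ratio, axis=0)
        f_f0_peak = float(np.nanmax(f_f0_sensor))

    blink_sensor = blink = None
    if "CaF_SR" in traces.data:
        caf_sr = traces.data["CaF_SR"]
        f0 = caf_sr[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            dff = np.where(f0 > 0, caf_sr / f0 - 1.0, np.nan)
        blink_sensor = np.abs(np.nanmin(dff, axis=0))
        blink = float(np.nanmax(blink_sensor))

    if source_x is None:
        source_x = float(traces.sensor_x.max())
    arrivals, dists = [], []
    for j in range(traces.n_sensors):
        at = _arrival_time(t, C[:, j], params.C_rest)
        if at is not None:
            arrivals.append(at)
            dists.append(abs(traces.sensor_x[j] - source_x))
    wave_speed = None
    if len(arrivals) >= 2 and np.ptp(arrivals) > 0:
        slope = np.polyfit(arrivals, dists, 1)[0]  # um per ms
        if slope > 0:
            wave_speed = float(slope * 1000.0)  # um/s

    # Termination: last time any sensor stays above rest + 10% of its own
    # peak excursion.
    termination = None
    exc = peak_c - params.C_rest
    active = np.zeros(len(t), dtype=bool)
    for j in range(traces.n_sensors):
        if exc[j] > 0:
            active |= C[:, j] > params.C_rest + 0.1 * exc[j]
    if active.any():
        termination = float(t[np.where(active)[0][-1]])

    return WaveSummary(
        sensor_x=np.asarray(traces.sensor_x, dtype=float),
        c_rest=params.C_rest,
        cs_rest=params.CS_rest,
        peak_c=peak_c,
        trough_cs=trough_cs,
        f_f0_peak_per_sensor=f_f0_sensor,
        f_f0_peak=f_f0_peak,
        blink_per_sensor=blink_sensor,
        blink_amplitude=blink,
        wave_speed=wave_speed,
        termination_time=termination,
    )


def compare_runs(a: WaveSummary, b: WaveSummary) -> Dict[str, object]:
    """Paired comparison of two runs on the same sensor layout.

    Returns per-sensor and aggregate measures of run ``b`` relative to run
    ``a``: peak suppression % (positive when b's cytosolic peaks are lower),
    SR-depletion change % (positive when b depletes less), mean absolute
    SR-trough discrepancy in uM, and the termination-time ratio b/a.
    ``compare_runs(a, b)`` and ``compare_runs(b, a)`` have reciprocal ratios
    and negated differences.
    """
    if len(a.sensor_x) != len(b.sensor_x) or not np.allclose(a.sensor_x, b.sensor_x):
        raise ValueError("sensor layouts differ; runs are not comparable")
    peak_suppr = (1.0 - b.peak_c / a.peak_c) * 100.0
    depl_a = a.depletion
    depl_b = b.depletion
    with np.errstate(divide="ignore", invalid="ignore"):
        depl_drop = (1.0 - depl_b / depl_a) * 100.0
    out: Dict[str, object] = {
        "peak_suppression_pct": peak_suppr,
        "peak_suppression_pct_mean": float(np.mean(peak_suppr)),
        "peak_suppression_pct_max": float(np.max(peak_suppr)),
        "depletion_drop_pct": depl_drop,
        "depletion_drop_pct_mean": float(np.mean(depl_drop)),
        "depletion_drop_pct_of_means": float(
            (1.0 - np.mean(depl_b) / np.mean(depl_a)) * 100.0
        ),
        "sr_trough_discrepancy_uM": np.abs(a.trough_cs - b.trough_cs),
        "sr_trough_discrepancy_uM_mean": float(np.mean(np.abs(a.trough_cs - b.trough_cs))),
    }
    if a.termination_time and b.termination_time:
        out["termination_ratio"] = float(b.termination_time / a.termination_time)
    return out
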