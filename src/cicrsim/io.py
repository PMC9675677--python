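"""Trace tables, snapshot containers and run manifests.

Traces travel as tidy delimited tables (time_ms, sensor_id, variable,
value_uM) via pandas; snapshots as ``.npz`` archives keyed by
``variable/time_ms``; a JSON run manifest records the fully resolved
configuration, seed and wall-clock interval so any run can be reproduced
bit-exactly.
"""

from __future__ import annotations

import datetime as _dt
import json
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .observables import SensorTraces

__all__ = [
    "traces_to_frame",
    "frame_to_traces",
    "write_traces",
    "read_traces",
    "write_snapshots",
    "read_snapshots",
    "RunManifest",
]


def traces_to_frame(traces: SensorTraces) -> pd.DataFrame:
    """Tidy long-format table: time_ms, sensor_id (1-based), variable, value_uM."""
    rows = []
    for var, arr in traces.data.items():
        for j in range(traces.n_sensors):
            rows.append(pd.DataFrame({
                "time_ms": traces.times,
                "sensor_id": j + 1,
                "sensor_x_um": traces.sensor_x[j],
                "variable": var,
                "value_uM": arr[:, j],
            }))
    return pd.concat(rows, ignore_index=True)


def frame_to_traces(frame: pd.DataFrame) -> SensorTraces:
    """Inverse of :func:`traces_to_frame`."""
    if frame.empty:
        raise ValueError("empty trace table")
    times = np.sort(frame["time_ms"].unique())
    sensor_ids = np.sort(frame["sensor_id"].unique())
    sensor_x = np.array([
        frame.loc[frame.sensor_id == s, "sensor_x_um"].iloc[0] for s in sensor_ids
    ])
    data: Dict[str, np.ndarray] = {}
    for var, sub in frame.groupby("variable", sort=False):
        arr = np.full((len(times), len(sensor_ids)), np.nan)
        piv = sub.pivot_table(index="time_ms", columns="sensor_id",
                              values="value_uM", sort=True)
        arr[:, :] = piv.reindex(index=times, columns=sensor_ids).to_numpy()
        data[str(var)] = arr
    return SensorTraces(times=times, data=data, sensor_x=sensor_x)


def write_traces(path, traces: SensorTraces) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path) -> SensorTraces:
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"trace file {path} is empty")
    return frame_to_traces(frame)


def write_snapshots(path, snapshots: Dict[str, Dict[float, np.ndarray]]) -> None:
    """Store snapshot fields as an .npz archive keyed ``variable/time_ms``."""
    arrays = {
        f"{var}/{t_ms:.6f}": arr
        for var, by_time in snapshots.items()
        for t_ms, arr in by_time.items()
    }
    np.savez(path, **arrays)


def read_snapshots(path) -> Dict[str, Dict[float, np.ndarray]]:
    out: Dict[str, Dict[float, np.ndarray]] = {}
    with np.load(path) as npz:
        for key in npz.files:
            var, t_str = key.rsplit("/", 1)
            out.setdefault(var, {})[float(t_str)] = npz[key]
    return out


class RunManifest:
    """Resolved configuration + seed + timing of one run, as JSON.

    Written (status "running") before the run starts and finalised after it
    ends, so an interrupted run is distinguishable and a finished one can be
    reproduced exactly from the recorded config and seed.
    """

    def __init__(self, path, meta: Dict[str, object],
                 outputs: Optional[Dict[str, str]] = None) -> None:
        from . import __version__

        self.path = path
        self.doc = {
            "software": "cicrsim",
            "version": __version__,
            "status": "running",
            "started_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
            "meta": meta,
            "outputs": outputs or {},
        }

    def _write(self) -> None:
        with open(self.path, "w", encoding="utf-8") as fh:
            json.dump(self.doc, fh, indent=2, default=_jsonable)
            fh.write("\n")

    def start(self) -> "RunManifest":
        self._write()
        return self

    def finalize(self, **extra: object) -> None:
        self.doc["status"] = "completed"
        self.doc["finished_utc"] = _dt.datetime.now(_dt.timezone.utc).isoformat()
        self.doc.update(extra)
        self._write()


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")
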