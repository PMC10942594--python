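"""Trace serialization: HDF5 containers and CSV raster export."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .network import SimulationTrace

__all__ = ["save_trace", "load_trace", "spikes_to_csv"]


def save_trace(trace: SimulationTrace, path, config_yaml: str | None = None):
    """Write a trace to an HDF5 file.

    Layout: per-population spike id/time arrays under ``spikes/<area>_<cls>``,
    scalar timeseries under ``series/``, and grid metadata (plus optionally
    the effective run configuration) as root attributes.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["dt_ms"] = trace.dt_ms
        f.attrs["duration_ms"] = trace.duration_ms
        if config_yaml is not None:
            f.attrs["config_yaml"] = config_yaml
        if trace.monitor_target is not None:
            f.attrs["monitor_area"] = trace.monitor_target[0]
            f.attrs["monitor_index"] = trace.monitor_target[1]
        sp = f.create_group("spikes")
        for (area, cls), s in trace.pop_slices.items():
            g = sp.create_group(f"{area}_{cls}")
            t, ids = trace.spikes_for(area, cls)
            g.create_dataset("t_ms", data=t)
            g.create_dataset("neuron", data=ids.astype(np.int32))
            g.attrs["n_neurons"] = s.stop - s.start
        se = f.create_group("series")
        se.create_dataset("theta_amplitude", data=trace.theta_amplitude)
        se.create_dataset("theta_phase", data=trace.theta_phase)
        se.create_dataset("theta_drive_na", data=trace.theta_drive_na)
        se.create_dataset("x_rate", data=trace.x_rate)
        se.create_dataset("stim_na", data=trace.stim_series_na)
        for name, arr in (("ican_na", trace.ican_mon_na),
                          ("im_na", trace.im_mon_na),
                          ("vm_mv", trace.vm_mon_mv)):
            if arr is not None:
                se.create_dataset(name, data=arr)
    return path


def load_trace(path) -> SimulationTrace:
    """Read a trace written by :func:`save_trace`."""
    with h5py.File(path, "r") as f:
        pop_slices = {}
        times, ids = [], []
        off = 0
        counts = {}
        for name in sorted(f["spikes"]):
            area, cls = name.rsplit("_", 1)
            g = f["spikes"][name]
            n = int(g.attrs["n_neurons"])
            pop_slices[(area, cls)] = slice(off, off + n)
            times.append(g["t_ms"][...])
            ids.append(g["neuron"][...].astype(np.int64) + off)
            counts.setdefault(area, [0, 0])
            counts[area][0 if cls == "E" else 1] = n
            off += n
        t = np.concatenate(times) if times else np.empty(0)
        i = np.concatenate(ids) if ids else np.empty(0, dtype=np.int64)
        order = np.argsort(t, kind="stable")
        se = f["series"]
        monitor = None
        if "monitor_area" in f.attrs:
            monitor = (str(f.attrs["monitor_area"]),
                       int(f.attrs["monitor_index"]))
        return SimulationTrace(
            dt_ms=float(f.attrs["dt_ms"]),
            duration_ms=float(f.attrs["duration_ms"]),
            spike_times_ms=t[order], spike_ids=i[order],
            pop_slices=pop_slices,
            counts={a: tuple(v) for a, v in counts.items()},
            theta_amplitude=se["theta_amplitude"][...],
            theta_phase=se["theta_phase"][...],
            theta_drive_na=se["theta_drive_na"][...],
            x_rate=se["x_rate"][...],
            stim_series_na=se["stim_na"][...],
            ican_mon_na=se["ican_na"][...] if "ican_na" in se else None,
            im_mon_na=se["im_na"][...] if "im_na" in se else None,
            vm_mon_mv=se["vm_mv"][...] if "vm_mv" in se else None,
            monitor_target=monitor)


def spikes_to_csv(trace: SimulationTrace, path):
    """Export the raster as CSV (area, class, neuron id, time in ms)."""
    import pandas as pd

    rows = []
    for (area, cls) in trace.pop_slices:
        t, ids = trace.spikes_for(area, cls)
        rows.append(pd.DataFrame({"area": area, "class": cls,
                                  "neuron": ids, "t_ms": t}))
    df = pd.concat(rows, ignore_index=True) if rows else \
        pd.DataFrame(columns=["area", "class", "neuron", "t_ms"])
    df.sort_values("t_ms", kind="stable").to_csv(path, index=False)
    return Path(path)
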