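"""Synthetic fixtures: slice geometry export, PAC test signals, toy spikes.

Everything here is generated programmatically and seed-reproducible; the
PAC signal generator is also the ground-truth source for the analysis
tests (a carrier whose amplitude is modulated by the phase of a slow
rhythm, with adjustable modulation depth).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .topology import Z_EXTENT_UM, default_slice_geometry

__all__ = [
    "make_pac_signal",
    "make_toy_spikes",
    "generate_fixtures",
]


def make_pac_signal(duration_s: float = 20.0, fs: float = 1000.0,
                    f_phase_hz: float = 6.0, f_amp_hz: float = 60.0,
                    depth: float = 1.0, noise_sd: float = 0.1,
                    seed: int = 0):
    """Phase-amplitude-coupled test signal.

    x(t) = (1 + depth·cos(2π f_p t))/2 · cos(2π f_a t) + slow + noise,
    so the fast carrier's amplitude peaks at the slow rhythm's peak
    (phase 0).  depth = 0 gives an unmodulated carrier.

    Returns (times_s, x).
    """
    if not 0 <= depth <= 1:
        raise ValueError("modulation depth must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    slow = np.cos(2 * np.pi * f_phase_hz * t)
    envelope = (1.0 + depth * slow) / 2.0
    x = envelope * np.cos(2 * np.pi * f_amp_hz * t) + 0.5 * slow
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=t.size)
    return t, x


def make_toy_spikes(n_neurons: int = 100, duration_s: float = 2.0,
                    rate_hz: float = 5.0, seed: int = 0):
    """Homogeneous-Poisson spike table: (neuron_ids, times_ms), sorted."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate_hz * duration_s, size=n_neurons)
    ids = np.repeat(np.arange(n_neurons), counts)
    times = rng.uniform(0.0, duration_s * 1000.0, size=counts.sum())
    order = np.argsort(times, kind="stable")
    return ids[order], times[order]


def generate_fixtures(kind: str, out_dir, params: dict | None = None,
                      seed: int = 0) -> list:
    """Write one fixture family to ``out_dir``; returns the paths written.

    Kinds: ``slice-geometry`` (polygon vertex tables per area/stratum plus
    a metadata JSON), ``pac-signal`` (CSV of t, x), ``spike-toy`` (CSV of
    neuron id, time).
    """
    params = dict(params or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if kind == "slice-geometry":
        geom = default_slice_geometry(params.get("scale_xy", 1.0))
        for area, strata in geom.items():
            for stratum, poly in strata.items():
                path = out_dir / f"slice_{area}_{stratum}.csv"
                xy = np.asarray(poly.exterior.coords)
                np.savetxt(path, xy, delimiter=",", header="x_um,y_um",
                           comments="")
                written.append(path)
        meta = out_dir / "slice_meta.json"
        meta.write_text(json.dumps({"z_extent_um": Z_EXTENT_UM,
                                    "areas": sorted(geom)}, indent=1))
        written.append(meta)
    elif kind == "pac-signal":
        t, x = make_pac_signal(seed=seed, **params)
        path = out_dir / "pac_signal.csv"
        np.savetxt(path, np.column_stack([t, x]), delimiter=",",
                   header="t_s,x", comments="")
        written.append(path)
    elif kind == "spike-toy":
        ids, times = make_toy_spikes(seed=seed, **params)
        path = out_dir / "spikes_toy.csv"
        np.savetxt(path, np.column_stack([ids, times]), delimiter=",",
                   header="neuron_id,t_ms", comments="", fmt="%d,%.3f")
        written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
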