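"""Closed-loop septo-hippocampal network: assembly, stimulation, simulation.

`build_network` places the neurons, wires the graph, prepares the jit engine
arrays and returns a runnable :class:`NetworkModel`.  The septal oscillator
ensemble injects the rectified-cosine theta drive into EC excitatory and
inhibitory cells; the instantaneous firing rate X(t) of CA1 excitatory cells
feeds back into the oscillators' reset term.  Electrical stimulation is an
intracellular current applied equally to all neurons of the targeted area.

Desk-scale mode: population sizes are multiplied by ``scale`` and synaptic
conductance increments by ``1/scale``, conserving the mean synaptic input so
the mean-field regimes of the full-size model are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from . import _engine
from .kuramoto import OscillatorEnsembleParams, init_ensemble, wrap_phase
from .neurons import (CellClassParams, build_gate_tables, excitatory_params,
                      inhibitory_params)
from .synapses import EXC_SYNAPSE, INH_SYNAPSE, SynapseParams, exact_propagators
from .topology import (A_INTER_DEFAULT, A_INTRA, SIGMA_INTER_UM,
                       SIGMA_INTRA_EXC_UM, SIGMA_INTRA_INH_UM, Z_EXTENT_UM,
                       PopulationLayout, ConnectivityGraph, build_graph,
                       default_counts, default_slice_geometry, place_neurons)

__all__ = [
    "NetworkConfig",
    "StimulusProtocol",
    "SimulationTrace",
    "NetworkModel",
    "build_network",
    "build_ei_circuit",
    "make_stimulus",
    "run_simulation",
    "firing_rate_feedback",
]

PHASE_TOL_RAD = 0.05


@dataclass(frozen=True)
class StimulusProtocol:
    """Intracellular current pulses delivered to one area.

    Modes
    -----
    ``times``  explicit pulse onsets (ms);
    ``phase``  a single pulse at the first crossing of ``phase_rad`` after
               ``arming_ms``;
    ``train``  pulses at ``train_hz`` for ``train_duration_ms``, the first
               at the requested onset phase (or at ``arming_ms`` if none).
    """

    target_area: str = "CA1"
    amplitude_na: float = 10.0
    pulse_width_ms: float = 1.0
    mode: str = "times"
    times_ms: tuple = ()
    phase_rad: float = 0.0
    arming_ms: float = 0.0
    train_hz: float = 6.0
    train_duration_ms: float = 2000.0
    onset_phase_rad: float | None = None

    def __post_init__(self):
        if not math.isfinite(self.amplitude_na):
            raise ValueError("stimulus amplitude must be finite")
        if self.mode not in ("times", "phase", "train"):
            raise ValueError(f"unknown stimulation mode {self.mode!r}")
        if self.mode == "train" and self.train_hz <= 0:
            raise ValueError("train frequency must be > 0")

    @property
    def needs_phase(self) -> bool:
        return self.mode == "phase" or (self.mode == "train"
                                        and self.onset_phase_rad is not None)


class ProtocolError(RuntimeError):
    """Raised when a phase-targeted protocol cannot be realized."""


def _first_phase_crossing(phase_series, target_rad, start_idx):
    d = wrap_phase(np.asarray(phase_series) - target_rad)
    for k in range(max(start_idx, 1), d.size):
        if abs(d[k]) < PHASE_TOL_RAD and d[k - 1] <= 0.0 <= d[k]:
            return k
        if d[k - 1] < 0.0 <= d[k] and (d[k] - d[k - 1]) < np.pi:
            return k
    raise ProtocolError(
        f"theta phase {target_rad:.3f} rad never crossed after "
        f"index {start_idx} (phase range "
        f"[{d.min():.2f}, {d.max():.2f}] rad around target)")


def make_stimulus(protocol: StimulusProtocol, n_steps: int, dt_ms: float,
                  theta_phase_series=None) -> np.ndarray:
    """Render a protocol into a per-step current series (nA).

    Phase-targeted modes require the theta phase series of a reference run
    (the closed-loop model realizes them with a matched no-stimulation pass).
    """
    stim = np.zeros(n_steps)
    width = max(1, int(round(protocol.pulse_width_ms / dt_ms)))

    def add_pulse(onset_idx):
        stim[onset_idx: min(onset_idx + width, n_steps)] = protocol.amplitude_na

    if protocol.mode == "times":
        onsets = [int(round(t / dt_ms)) for t in protocol.times_ms]
    else:
        if protocol.needs_phase and theta_phase_series is None:
            raise ProtocolError("phase-targeted stimulation requires a theta "
                                "phase series")
        arm = int(round(protocol.arming_ms / dt_ms))
        if protocol.mode == "phase":
            onsets = [_first_phase_crossing(theta_phase_series,
                                            protocol.phase_rad, arm)]
        else:  # train
            if protocol.onset_phase_rad is None:
                first = arm
            else:
                first = _first_phase_crossing(theta_phase_series,
                                              protocol.onset_phase_rad, arm)
            period = 1000.0 / protocol.train_hz
            n_pulses = int(math.floor(protocol.train_duration_ms / period + 1e-9))
            onsets = [first + int(round(i * period / dt_ms))
                      for i in range(max(n_pulses, 1))]
    for o in onsets:
        if 0 <= o < n_steps:
            add_pulse(o)
    return stim


def firing_rate_feedback(spike_times_ms, n_neurons: int, tau_fr_ms: float,
                         dt_ms: float, n_steps: int, x0: float = 0.0):
    """Reference exponential-kernel instantaneous rate X(t), in 1/s.

    Each spike adds 1/(N·τ_FR); between spikes X decays with time constant
    τ_FR.  This is the same update the engine applies online.
    """
    if tau_fr_ms <= 0:
        raise ValueError("tau_FR must be > 0")
    counts = np.zeros(n_steps)
    idx = np.floor(np.asarray(spike_times_ms, dtype=float) / dt_ms).astype(int)
    np.add.at(counts, idx[(idx >= 0) & (idx < n_steps)], 1.0)
    decay = np.exp(-dt_ms / tau_fr_ms)
    jump = 1.0 / (n_neurons * tau_fr_ms * 1e-3)
    x = np.empty(n_steps)
    acc = x0
    for k in range(n_steps):
        acc = acc * decay + counts[k] * jump
        x[k] = acc
    return x


# ---------------------------------------------------------------------------
# configuration and trace containers
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Everything needed to build and run the closed-loop model."""

    oscillator: OscillatorEnsembleParams = field(
        default_factory=OscillatorEnsembleParams)
    counts: dict | None = None           # {area: (nE, nI)}; default Table sizes
    scale: float = 1.0
    compensate_increments: bool = True   # per-class in-degree compensation
    z_extent_um: float | None = None     # None -> 15 mm x min(scale, 1)
    geometry_scale_xy: float = 1.0
    reference_counts: dict | None = None  # full-size counts for compensation
    a_inter: dict = field(default_factory=lambda: dict(A_INTER_DEFAULT))
    a_intra: dict | None = None
    exc_params: CellClassParams = field(default_factory=excitatory_params)
    inh_params: CellClassParams = field(default_factory=inhibitory_params)
    exc_synapse: SynapseParams = EXC_SYNAPSE
    inh_synapse: SynapseParams = INH_SYNAPSE
    dt_ms: float = 0.1
    duration_ms: float = 3000.0
    burn_in_ms: float = 0.0
    reset_on: bool = True
    noise_on: bool = True
    seed: int = 0
    init_vm_range_mv: tuple = (-70.0, -60.0)
    lloyd_iters: int = 30
    spike_rate_allowance_hz: float = 400.0
    monitor: tuple = ("CA1", 0)          # (area, E-cell local index) | None

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        if self.duration_ms <= self.burn_in_ms:
            raise ValueError("duration must exceed burn-in")


@dataclass
class SimulationTrace:
    """Spikes, septal state and monitors on the fixed simulation grid."""

    dt_ms: float
    duration_ms: float
    spike_times_ms: np.ndarray
    spike_ids: np.ndarray                # engine order: [E areas... | I areas...]
    pop_slices: dict                     # (area, "E"/"I") -> engine slice
    counts: dict
    theta_amplitude: np.ndarray
    theta_phase: np.ndarray
    theta_drive_na: np.ndarray
    x_rate: np.ndarray
    stim_series_na: np.ndarray
    ican_mon_na: np.ndarray | None = None
    im_mon_na: np.ndarray | None = None
    vm_mon_mv: np.ndarray | None = None
    monitor_target: tuple | None = None

    @property
    def n_steps(self) -> int:
        return self.theta_phase.size

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt_ms

    def spikes_for(self, area: str, cls: str):
        """(times, local neuron ids) of one population."""
        s = self.pop_slices[(area, cls)]
        m = (self.spike_ids >= s.start) & (self.spike_ids < s.stop)
        return self.spike_times_ms[m], self.spike_ids[m] - s.start

    def mean_rate_hz(self, area: str, cls: str, t_from_ms: float = 0.0,
                     t_to_ms: float | None = None) -> float:
        """Mean population firing rate in a window: spikes/(time × neurons)."""
        t_to_ms = self.duration_ms if t_to_ms is None else t_to_ms
        times, _ = self.spikes_for(area, cls)
        n = self.pop_slices[(area, cls)].stop - self.pop_slices[(area, cls)].start
        nsp = int(((times >= t_from_ms) & (times < t_to_ms)).sum())
        return nsp / ((t_to_ms - t_from_ms) * 1e-3 * n)


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _provenance_segments(prov: np.ndarray):
    """(class name, lo, hi) runs of the piecewise-constant provenance array."""
    if prov.size == 0:
        return []
    change = np.flatnonzero(prov[1:] != prov[:-1])
    bounds = np.concatenate([[0], change + 1, [prov.size]])
    return [(prov[lo], int(lo), int(hi))
            for lo, hi in zip(bounds[:-1], bounds[1:])]


class NetworkModel:
    """A built, runnable septo-hippocampal model (see :func:`build_network`)."""

    def __init__(self, config: NetworkConfig, layout: PopulationLayout,
                 intra_graph: ConnectivityGraph, inter_parts: dict,
                 compensation: dict | None = None,
                 _carry: "NetworkModel | None" = None):
        self.config = config
        self.layout = layout
        self.intra_graph = intra_graph
        self.inter_parts = inter_parts
        self._graph_key = (id(intra_graph),
                           tuple(sorted((k, id(g))
                                        for k, g in inter_parts.items())))
        self.graph = ConnectivityGraph.concatenate(
            [intra_graph, *inter_parts.values()])
        self.areas = [a for a in ("EC", "DG", "CA3", "CA1")
                      if a in {k[0] for k in layout.slices}]
        self.compensation = (self._compensation_factors()
                             if compensation is None else compensation)
        self._prepare(_carry)

    # -- desk-scale increment compensation --------------------------------
    def _compensation_factors(self) -> dict:
        """Per-projection-class weight factors for desk-scale networks.

        Desk-scale networks shrink the slice thickness together with the
        populations, which preserves volumetric density and hence the local
        (short-σ) in-degrees; long-range kernels lose in-degree to boundary
        truncation.  Each class's increment is multiplied by the ratio of
        the expected full-size in-degree to the expected desk-scale
        in-degree (Monte-Carlo over the connection kernel at the published
        reference gains, full vs. desk z-extent), so the mean synaptic
        input per target neuron is conserved class by class.  Factors are
        computed once per layout and frozen while gains are retuned.
        """
        cfg = self.config
        if not cfg.compensate_increments or cfg.scale >= 1.0:
            return {}
        ref_counts = cfg.reference_counts or default_counts(1.0)
        a_intra = cfg.a_intra or A_INTRA
        z_desk = (cfg.z_extent_um if cfg.z_extent_um is not None
                  else Z_EXTENT_UM * min(cfg.scale, 1.0))
        m = 20_000
        present = {k[0] for k in self.layout.slices}
        from .topology import AREAS

        comp = {}
        # within-area classes (per-class rng: factors are independent of
        # evaluation order)
        for ai, area in enumerate(a for a in AREAS if a in present):
            for pi, (pair, amax) in enumerate(sorted(
                    a_intra.get(area, {}).items())):
                if amax <= 0:
                    continue
                rng = np.random.default_rng([cfg.seed, 777, 1, ai, pi])

                def dz2(extent):
                    return (rng.uniform(0, extent, m)
                            - rng.uniform(0, extent, m)) ** 2
                pre_cls, post_cls = pair.split("->")
                sigma = (SIGMA_INTRA_EXC_UM if pre_cls == "E"
                         else SIGMA_INTRA_INH_UM)
                i_pre = 0 if pre_cls == "E" else 1
                s_pre = self.layout.block(area, pre_cls)
                s_post = self.layout.block(area, post_cls)
                xy_pre = self.layout.positions_um[s_pre, :2]
                xy_post = self.layout.positions_um[s_post, :2]
                dxy2 = ((xy_pre[rng.integers(0, xy_pre.shape[0], m)]
                         - xy_post[rng.integers(0, xy_post.shape[0], m)]) ** 2
                        ).sum(1)
                k_full = np.exp(-(dxy2 + dz2(Z_EXTENT_UM)) / (2 * sigma ** 2))
                k_desk = np.exp(-(dxy2 + dz2(z_desk)) / (2 * sigma ** 2))
                n_full = ref_counts[area][i_pre] * amax * k_full.mean()
                n_desk = ((s_pre.stop - s_pre.start) * amax * k_desk.mean())
                comp[f"intra:{area}:{pair}"] = n_full / max(n_desk, 1e-12)
        # between-area classes.  Expected input per target is
        # gain × N_pre × E[exp(−Δz²/2σ²)] × w at either scale (the clipped
        # probability excess is carried by the edge weights), so the gain
        # cancels and the factor is the kernel-mass ratio alone.
        for ci, (src, dst) in enumerate(sorted(A_INTER_DEFAULT)):
            if src not in present or dst not in present:
                continue
            rng = np.random.default_rng([cfg.seed, 777, 2, ci])

            def dz2(extent):
                return (rng.uniform(0, extent, m)
                        - rng.uniform(0, extent, m)) ** 2

            s_pre = self.layout.block(src, "E")
            k_full = np.exp(-dz2(Z_EXTENT_UM) / (2 * SIGMA_INTER_UM ** 2))
            k_desk = np.exp(-dz2(z_desk) / (2 * SIGMA_INTER_UM ** 2))
            n_full = ref_counts[src][0] * k_full.mean()
            n_desk = (s_pre.stop - s_pre.start) * k_desk.mean()
            factor = n_full / max(n_desk, 1e-12)
            comp[f"inter:{src}->{dst}:E->E"] = factor
            comp[f"inter:{src}->{dst}:E->I"] = factor
        return comp

    def with_updates(self, compensation: dict | None = None,
                     **config_changes) -> "NetworkModel":
        """New model sharing this layout, with config fields replaced.

        A changed ``a_inter`` re-samples only the projection classes whose
        gain actually changed (per-class seeds); compensation factors are
        inherited (frozen) unless explicitly supplied.
        """
        from .topology import connect_inter_class

        new_cfg = replace(self.config, **config_changes)
        intra = self.intra_graph
        if "a_intra" in config_changes:
            from .topology import connect_intra
            intra = connect_intra(self.layout, seed=new_cfg.seed,
                                  a_intra=new_cfg.a_intra)
        inter_parts = dict(self.inter_parts)
        if "a_inter" in config_changes:
            present = {k[0] for k in self.layout.slices}
            old_gains = self.config.a_inter
            for (src, dst), gain in new_cfg.a_inter.items():
                if src not in present or dst not in present:
                    continue
                if gain != old_gains.get((src, dst)):
                    for post_cls in ("E", "I"):
                        inter_parts[(src, dst, post_cls)] = connect_inter_class(
                            self.layout, src, dst, post_cls, gain,
                            seed=new_cfg.seed)
            for key in list(inter_parts):
                if (key[0], key[1]) not in new_cfg.a_inter:
                    del inter_parts[key]
        return NetworkModel(new_cfg, self.layout, intra, inter_parts,
                            compensation=(self.compensation
                                          if compensation is None
                                          else compensation),
                            _carry=self)

    # -- engine array preparation ----------------------------------------
    def _prepare(self, carry: "NetworkModel | None" = None):
        cfg = self.config
        lay = self.layout
        if carry is not None and carry._graph_key == self._graph_key \
                and carry.compensation == self.compensation:
            # graph and weights unchanged: reuse the prepared CSR and layout
            for attr in ("pop_slices", "_to_engine", "nE", "nI", "areaE",
                         "areaI", "indptr", "post_idx", "w_us"):
                setattr(self, attr, getattr(carry, attr))
        else:
            # engine order: all E blocks (area order), then all I blocks
            order = []
            self.pop_slices = {}
            off = 0
            for cls in ("E", "I"):
                for a in self.areas:
                    s = lay.block(a, cls)
                    n = s.stop - s.start
                    order.append(np.arange(s.start, s.stop))
                    self.pop_slices[(a, cls)] = slice(off, off + n)
                    off += n
            order = np.concatenate(order)
            self._to_engine = np.empty(lay.n, dtype=np.int64)
            self._to_engine[order] = np.arange(lay.n)

            self.nE = sum(self.pop_slices[(a, "E")].stop
                          - self.pop_slices[(a, "E")].start
                          for a in self.areas)
            self.nI = lay.n - self.nE
            self.areaE = np.concatenate([
                np.full(self.pop_slices[(a, "E")].stop
                        - self.pop_slices[(a, "E")].start, i, dtype=np.int64)
                for i, a in enumerate(self.areas)])
            self.areaI = np.concatenate([
                np.full(self.pop_slices[(a, "I")].stop
                        - self.pop_slices[(a, "I")].start, i, dtype=np.int64)
                for i, a in enumerate(self.areas)]) if self.nI \
                else np.empty(0, np.int64)

            pre = self._to_engine[self.graph.pre]
            post = self._to_engine[self.graph.post]
            w_us = self.graph.weight_ps * 1e-6
            if self.compensation:
                w_us = w_us.copy()
                for name, lo, hi in _provenance_segments(self.graph.provenance):
                    w_us[lo:hi] *= self.compensation.get(name, 1.0)
            csr = sp.csr_matrix((w_us, (pre, post)), shape=(lay.n, lay.n))
            self.indptr = csr.indptr.astype(np.int64)
            self.post_idx = csr.indices.astype(np.int64)
            self.w_us = csr.data.astype(np.float64)

        self.tabE = build_gate_tables(cfg.exc_params, cfg.dt_ms)
        self.tabI = build_gate_tables(cfg.inh_params, cfg.dt_ms)

        e, i = cfg.exc_params, cfg.inh_params
        self.constE = np.array([
            e.conductance_us(e.g_L), e.E_L, e.conductance_us(e.g_K), e.E_K,
            e.conductance_us(e.g_Na), e.E_Na, e.conductance_us(e.g_Ca), e.E_Ca,
            e.conductance_us(e.g_CAN), e.E_CAN, e.conductance_us(e.g_M), e.E_M,
            e.capacitance_nf,
            e.gamma_factor, e.ca_inf_mm, e.tau_ca_ms,
            1.4 / e.ca_crit_mm, 0.0002 * np.exp(1.4)])
        self.constI = np.array([
            i.conductance_us(i.g_L), i.E_L, i.conductance_us(i.g_K), i.E_K,
            i.conductance_us(i.g_Na), i.E_Na, i.capacitance_nf])

        self.theta_area = self.areas.index("EC") if "EC" in self.areas else -1
        s = self.pop_slices.get(("CA1", "E"))
        if s is not None:
            self.ca1e_lo, self.ca1e_hi = s.start, s.stop
            self.n_ca1e = s.stop - s.start
        else:
            self.ca1e_lo = self.ca1e_hi = -1
            self.n_ca1e = 1

    # -- running ----------------------------------------------------------
    def run(self, protocol: StimulusProtocol | None = None,
            ext_currents: dict | None = None,
            duration_ms: float | None = None,
            seed: int | None = None,
            stim_series: np.ndarray | None = None) -> SimulationTrace:
        """Integrate the closed loop.

        ``ext_currents`` maps area → (series_E, series_I) additional currents
        (nA, scalar or per-step).  Phase-targeted protocols are realized with
        a two-pass scheme: a matched no-stimulation run supplies the theta
        phase series used to position the pulses, then the stimulated run is
        repeated with identical seeds.
        """
        cfg = self.config
        duration = cfg.duration_ms if duration_ms is None else duration_ms
        n_steps = int(round(duration / cfg.dt_ms))
        seed = cfg.seed if seed is None else seed

        if stim_series is None and protocol is not None and protocol.needs_phase:
            ref = self.run(protocol=None, ext_currents=ext_currents,
                           duration_ms=duration, seed=seed)
            stim_series = make_stimulus(protocol, n_steps, cfg.dt_ms,
                                        theta_phase_series=ref.theta_phase)
        if stim_series is None:
            if protocol is not None:
                stim_series = make_stimulus(protocol, n_steps, cfg.dt_ms)
            else:
                stim_series = np.zeros(n_steps)
        stim_area = self.areas.index(protocol.target_area) if protocol else -1
        if protocol and protocol.target_area not in self.areas:
            raise ValueError(f"unknown stimulation target {protocol.target_area!r}")

        n_areas = len(self.areas)
        ext_e = np.zeros((n_steps, n_areas))
        ext_i = np.zeros((n_steps, n_areas))
        if ext_currents:
            for area, (se, si) in ext_currents.items():
                j = self.areas.index(area)
                ext_e[:, j] += np.broadcast_to(np.asarray(se, dtype=float),
                                               (n_steps,))
                ext_i[:, j] += np.broadcast_to(np.asarray(si, dtype=float),
                                               (n_steps,))

        rng = np.random.default_rng(seed)
        vE = rng.uniform(*cfg.init_vm_range_mv, size=self.nE)
        vI = rng.uniform(*cfg.init_vm_range_mv, size=self.nI)
        from .neurons import gate_steady_tau, can_rates
        gE_gates = np.empty((6, self.nE))
        for r, g in enumerate(self.tabE["gates"]):
            gE_gates[r] = gate_steady_tau(vE, g, cfg.exc_params)[0]
        ca = np.full(self.nE, cfg.exc_params.ca_inf_mm)
        a, b = can_rates(ca, cfg.exc_params)
        mcan = a / (a + b)
        gI_gates = np.empty((3, max(self.nI, 1)))
        for r, g in enumerate(self.tabI["gates"]):
            gI_gates[r] = gate_steady_tau(vI, g, cfg.inh_params)[0] \
                if self.nI else 0.0
        lastE = np.full(self.nE, -1e9)
        lastI = np.full(max(self.nI, 1), -1e9)

        osc_params = cfg.oscillator
        ens = init_ensemble(replace(osc_params, seed=osc_params.seed + seed + 1))
        theta = ens.phases_rad.copy()
        omega = ens.natural_freqs_rad_s.copy()

        eg_e, eh_e, c_e = exact_propagators(cfg.exc_synapse, cfg.dt_ms)
        eg_i, eh_i, c_i = exact_propagators(cfg.inh_synapse, cfg.dt_ms)
        n_tot = self.nE + self.nI
        ge = np.zeros(n_tot)
        he = np.zeros(n_tot)
        gi = np.zeros(n_tot)
        hi = np.zeros(n_tot)

        cap = int(n_tot * duration * 1e-3 * cfg.spike_rate_allowance_hz) + 1_000
        spike_t = np.empty(cap)
        spike_id = np.empty(cap, dtype=np.int64)
        theta_amp = np.empty(n_steps)
        theta_phase = np.empty(n_steps)
        theta_drive = np.empty(n_steps)
        x_series = np.empty(n_steps)
        ican = np.zeros(n_steps)
        im = np.zeros(n_steps)
        vm = np.zeros(n_steps)
        mon_idx = -1
        if cfg.monitor is not None and (cfg.monitor[0], "E") in self.pop_slices:
            mon_idx = self.pop_slices[(cfg.monitor[0], "E")].start + cfg.monitor[1]

        from .neurons import noise_step_sd_mv
        nsd_e = noise_step_sd_mv(cfg.exc_params, cfg.dt_ms) \
            if cfg.noise_on else 0.0
        nsd_i = noise_step_sd_mv(cfg.inh_params, cfg.dt_ms) \
            if cfg.noise_on else 0.0
        noise_scale = 1.0
        use_noise = nsd_e > 0 or nsd_i > 0
        noise_rng = np.random.default_rng([seed, 0xA5])
        dummy = np.zeros((1, 1), dtype=np.float32)

        chunk = 4000
        count = 0
        x0 = 0.0
        k0 = 0
        while k0 < n_steps:
            kc = min(chunk, n_steps - k0)
            if use_noise:
                nz_e = noise_rng.standard_normal((kc, self.nE),
                                                 dtype=np.float32)
                nz_e *= np.float32(nsd_e * noise_scale)
                nz_i = noise_rng.standard_normal((kc, max(self.nI, 1)),
                                                 dtype=np.float32)
                nz_i *= np.float32(nsd_i * noise_scale)
            else:
                nz_e = nz_i = dummy
            count, status, t_end, x0 = _engine.run_chunk(
                k0, kc, cfg.dt_ms,
                vE, gE_gates, mcan, ca, lastE, self.areaE,
                vI, gI_gates, lastI, self.areaI,
                self.constE, self.constI,
                self.tabE["x_inf"], self.tabE["e_fac"],
                self.tabI["x_inf"], self.tabI["e_fac"],
                self.tabE["v_min"], 1.0 / self.tabE["dv"],
                ge, he, gi, hi,
                eg_e, eh_e, c_e, eg_i, eh_i, c_i,
                cfg.exc_synapse.reversal_mv, cfg.inh_synapse.reversal_mv,
                self.indptr, self.post_idx, self.w_us,
                ext_e[k0:k0 + kc], ext_i[k0:k0 + kc],
                nz_e, nz_i, use_noise,
                theta, omega, osc_params.sync_ratio,
                osc_params.reset_gain, osc_params.theta_gain_na,
                osc_params.peak_phase_rad, osc_params.phase_offset_rad,
                osc_params.rate_time_constant_ms, x0,
                self.theta_area, float(self.n_ca1e),
                self.ca1e_lo, self.ca1e_hi, cfg.reset_on,
                stim_series[k0:k0 + kc], stim_area,
                mon_idx,
                theta_amp[k0:k0 + kc], theta_phase[k0:k0 + kc],
                theta_drive[k0:k0 + kc], x_series[k0:k0 + kc],
                spike_t, spike_id, count, ican[k0:k0 + kc],
                im[k0:k0 + kc], vm[k0:k0 + kc],
            )
            if status < 0:
                if status == -(n_tot + 1):
                    raise SimulationError(
                        f"spike buffer overflow at t={t_end:.1f} ms "
                        f"(cap {cap}); raise spike_rate_allowance_hz")
                raise SimulationError(
                    f"numeric blow-up in neuron {-status - 1} at "
                    f"t={t_end:.1f} ms")
            k0 += kc

        return SimulationTrace(
            dt_ms=cfg.dt_ms, duration_ms=duration,
            spike_times_ms=spike_t[:count].copy(),
            spike_ids=spike_id[:count].copy(),
            pop_slices=dict(self.pop_slices),
            counts={a: (self.pop_slices[(a, "E")].stop - self.pop_slices[(a, "E")].start,
                        self.pop_slices[(a, "I")].stop - self.pop_slices[(a, "I")].start)
                    for a in self.areas},
            theta_amplitude=theta_amp, theta_phase=theta_phase,
            theta_drive_na=theta_drive, x_rate=x_series,
            stim_series_na=stim_series,
            ican_mon_na=ican if mon_idx >= 0 else None,
            im_mon_na=im if mon_idx >= 0 else None,
            vm_mon_mv=vm if mon_idx >= 0 else None,
            monitor_target=cfg.monitor)


def build_network(config: NetworkConfig) -> NetworkModel:
    """Place neurons, wire the graph and return a runnable model."""
    counts = config.counts or default_counts(config.scale)
    geometry = default_slice_geometry(config.geometry_scale_xy)
    z_extent = (config.z_extent_um if config.z_extent_um is not None
                else Z_EXTENT_UM * min(config.scale, 1.0))
    sub = {a: counts[a] for a in counts}
    layout = place_neurons({a: geometry[a] for a in sub}, sub,
                           seed=config.seed, lloyd_iters=config.lloyd_iters,
                           z_extent_um=z_extent)
    from .topology import connect_inter_class, connect_intra
    intra = connect_intra(layout, seed=config.seed, a_intra=config.a_intra)
    inter_parts = {}
    for (src, dst), gain in sorted(config.a_inter.items()):
        if src not in sub or dst not in sub:
            continue
        for post_cls in ("E", "I"):
            inter_parts[(src, dst, post_cls)] = connect_inter_class(
                layout, src, dst, post_cls, gain, seed=config.seed)
    return NetworkModel(config, layout, intra, inter_parts)


def build_ei_circuit(n_exc: int = 1000, n_inh: int = 100, seed: int = 0,
                     **config_overrides) -> NetworkModel:
    """Reduced pyramidal–interneuron circuit with CA1-like coupling.

    The circuit is compact (point-like geometry), i.e. the D→0 limit of the
    spatial rules where connection probabilities equal the within-area
    maxima, and receives no septal drive; inputs are supplied per run via
    ``ext_currents`` or stimulation protocols.
    """
    defaults = dict(
        counts={"CA1": (n_exc, n_inh)},
        oscillator=OscillatorEnsembleParams(theta_gain_na=0.0, reset_gain=0.0,
                                            n_oscillators=10),
        geometry_scale_xy=0.005,
        z_extent_um=30.0,
        scale=1.0,
        compensate_increments=False,
        lloyd_iters=2,
        seed=seed,
    )
    defaults.update(config_overrides)
    return build_network(NetworkConfig(**defaults))


def run_simulation(model: NetworkModel,
                   protocol: StimulusProtocol | None = None,
                   seed: int | None = None, **kwargs) -> SimulationTrace:
    """Convenience wrapper: integrate the model under a protocol."""
    return model.run(protocol=protocol, seed=seed, **kwargs)
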