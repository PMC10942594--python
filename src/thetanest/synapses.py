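"""Biexponential conductance synapses.

AMPA-like (excitatory) and GABA-A-like (inhibitory) synapses follow the
rise/decay cascade

    I_syn = g (V_m − E_rev)
    dg/dt = (−g + h)/τ_g
    dh/dt = −h/τ_h

where a presynaptic spike increments ``h`` by a fixed, connection-specific
amount (pS).  The cascade is linear, so it is propagated EXACTLY over each
timestep (matrix exponential of the 2×2 system), which makes the engine's
conductance traces agree with the closed-form biexponential to machine
precision regardless of dt.

The per-connection increments of the reference parameterization are exposed
as ``INTRA_INCREMENTS_PS`` (within-area, by connection class) and
``INTER_INCREMENTS_PS`` (between areas, excitatory projections only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynapseParams",
    "EXC_SYNAPSE",
    "INH_SYNAPSE",
    "INTRA_INCREMENTS_PS",
    "INTER_INCREMENTS_PS",
    "synapse_step",
    "on_presynaptic_spike",
    "exact_propagators",
    "biexp_conductance",
    "biexp_peak_time",
]


@dataclass(frozen=True)
class SynapseParams:
    """Kinetics of one synapse type (reversal in mV, time constants in ms)."""

    reversal_mv: float
    rise_ms: float
    decay_ms: float

    def __post_init__(self):
        if self.rise_ms <= 0 or self.decay_ms <= 0:
            raise ValueError("synaptic time constants must be > 0")


# Rise/decay and reversal defaults are inherited constants of the source
# model family (AMPA-like and GABA-A-like); the paper prints the increments
# (tables below) but not the kinetics.  Exposed in the run config.  The
# 3 ms AMPA decay keeps the closed septo-hippocampal loop in its graded
# oscillatory regime (a 5 ms decay tips the loop into runaway once the
# feedback closes).
EXC_SYNAPSE = SynapseParams(reversal_mv=0.0, rise_ms=0.3, decay_ms=3.0)
INH_SYNAPSE = SynapseParams(reversal_mv=-80.0, rise_ms=1.0, decay_ms=10.0)

# Conductance increment (pS) applied to the postsynaptic h on a presynaptic
# spike, for connections WITHIN one area.  Missing keys = no connection.
INTRA_INCREMENTS_PS = {
    "EC":  {"E->I": 20.0, "I->E": 600.0},
    "DG":  {"E->I": 180.0, "I->E": 1800.0},
    "CA3": {"E->E": 20.0, "E->I": 20.0, "I->E": 600.0},
    "CA1": {"E->I": 60.0, "I->E": 1800.0, "I->I": 1800.0},
}

# Increments (pS) for projections BETWEEN areas (source excitatory cells onto
# both target populations).  Missing keys = no anatomical projection.
INTER_INCREMENTS_PS = {
    ("EC", "DG"): 20.0,
    ("EC", "CA3"): 20.0,
    ("EC", "CA1"): 20.0,
    ("DG", "CA3"): 180.0,
    ("CA3", "CA1"): 20.0,
    ("CA1", "EC"): 60.0,
}


def exact_propagators(params: SynapseParams, dt_ms: float):
    """Coefficients (eg, eh, c) of the exact one-step update.

    h(t+dt) = eh·h(t)
    g(t+dt) = eg·g(t) + c·h(t)

    with c = τ_h/(τ_h−τ_g)·(eh−eg) for τ_g ≠ τ_h (limit dt/τ·e^{−dt/τ} at
    equal time constants, the critically-damped alpha synapse).
    """
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    tg, th = params.rise_ms, params.decay_ms
    eg = np.exp(-dt_ms / tg)
    eh = np.exp(-dt_ms / th)
    if abs(th - tg) < 1e-12 * max(th, tg):
        c = dt_ms / tg * np.exp(-dt_ms / tg)
    else:
        c = th / (th - tg) * (eh - eg)
    return eg, eh, c


def synapse_step(g, h, dt_ms: float, params: SynapseParams):
    """Propagate (g, h) exactly over one step of length ``dt_ms``."""
    eg, eh, c = exact_propagators(params, dt_ms)
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    return eg * g + c * h, eh * h


def on_presynaptic_spike(h, increment):
    """A presynaptic spike adds the fixed conductance increment to h."""
    return np.asarray(h, dtype=float) + increment


def biexp_conductance(t_ms, weight, params: SynapseParams):
    """Closed-form g(t) after a single spike of weight w at t = 0.

    g(t) = w·τ_h/(τ_h−τ_g)·(e^{−t/τ_h} − e^{−t/τ_g}) for τ_g ≠ τ_h;
    the oracle against which the stepped propagation is checked.
    """
    t = np.asarray(t_ms, dtype=float)
    tg, th = params.rise_ms, params.decay_ms
    if abs(th - tg) < 1e-12 * max(th, tg):
        return weight * t / tg * np.exp(-t / tg)
    return weight * th / (th - tg) * (np.exp(-t / th) - np.exp(-t / tg))


def biexp_peak_time(params: SynapseParams) -> float:
    """Time to peak of the biexponential: τ_g τ_h/(τ_h−τ_g)·ln(τ_h/τ_g)."""
    tg, th = params.rise_ms, params.decay_ms
    if abs(th - tg) < 1e-12 * max(th, tg):
        return tg
    return tg * th / (th - tg) * np.log(th / tg)
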