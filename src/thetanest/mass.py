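"""Wilson–Cowan neural mass coupled to the septal oscillator ensemble.

A fast, generalizable reference model: a single excitatory/inhibitory
firing-rate mass

    τ_E dE/dt = −E + f(g_E θ_E + W_EE E − W_IE I + stim_E(t))
    τ_I dI/dt = −I + f(g_I θ_I + W_EI E)

with the logistic response f(x) = 1/(1 + e^{−β(x−x_m)}), driven by the same
Kuramoto ensemble used for the spiking model.  The theta drive enters the
excitatory mass through ``g_E·θ_E`` (the rectified-cosine ensemble output
normalized to [0, 1]); the excitatory activity E(t) stands in for the CA1
rate in the oscillators' reset term.  Because E ∈ (0, 1) rather than a
firing rate in 1/s, the reset gain is much larger than in the spiking model
(default 90 vs 4).

This mass model reproduces theta-nested gamma bursts and stimulation-evoked
theta phase reset without any conductance-based machinery, showing that the
reset behavior follows from the oscillator-ensemble coupling rather than
from single-cell details.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kuramoto import (OscillatorEnsembleParams, OscillatorEnsembleState,
                       init_ensemble, order_parameter, step_ensemble)

__all__ = [
    "MassParams",
    "MassState",
    "sigmoid_response",
    "step_mass_model",
    "run_mass_model",
]


def _default_mass_oscillators() -> OscillatorEnsembleParams:
    return OscillatorEnsembleParams(
        n_oscillators=100, center_frequency_hz=4.0, frequency_sd_hz=0.5,
        sync_ratio=25.0, reset_gain=90.0, theta_gain_na=1.0)


@dataclass(frozen=True)
class MassParams:
    """Wilson–Cowan parameters (times in ms; weights dimensionless)."""

    tau_e_ms: float = 3.2
    tau_i_ms: float = 3.2
    g_e: float = 0.7
    g_i: float = 0.0
    w_ee: float = 4.8
    w_ei: float = 4.0
    w_ie: float = 4.0
    w_ii: float = 0.0
    beta: float = 4.0
    x_m: float = 1.0
    oscillators: OscillatorEnsembleParams = field(
        default_factory=_default_mass_oscillators)

    def __post_init__(self):
        if self.tau_e_ms <= 0 or self.tau_i_ms <= 0:
            raise ValueError("mass time constants must be > 0")


@dataclass
class MassState:
    e: float
    i: float
    oscillators: OscillatorEnsembleState


def sigmoid_response(x, beta: float = 4.0, x_m: float = 1.0):
    """Logistic response f(x) = 1/(1+e^{−β(x−x_m)}), in (0, 1)."""
    return 1.0 / (1.0 + np.exp(-beta * (np.asarray(x, dtype=float) - x_m)))


def init_mass_state(params: MassParams) -> MassState:
    return MassState(e=0.0, i=0.0, oscillators=init_ensemble(params.oscillators))


def step_mass_model(state: MassState, params: MassParams, stim_e: float = 0.0,
                    dt_ms: float = 0.01) -> MassState:
    """One explicit-Euler step of the coupled mass/oscillator system.

    The oscillator ensemble consumes E(t) as its reset input and supplies
    the normalized rectified-cosine drive θ_E = (A cos φ + 1)/2 ∈ [0, 1].
    """
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    op = order_parameter(state.oscillators)
    theta_e = (op.amplitude * np.cos(op.phase_rad) + 1.0) / 2.0
    fe = sigmoid_response(params.g_e * theta_e + params.w_ee * state.e
                          - params.w_ie * state.i + stim_e,
                          params.beta, params.x_m)
    fi = sigmoid_response(params.g_i * theta_e + params.w_ei * state.e
                          - params.w_ii * state.i,
                          params.beta, params.x_m)
    e_new = state.e + dt_ms * (-state.e + float(fe)) / params.tau_e_ms
    i_new = state.i + dt_ms * (-state.i + float(fi)) / params.tau_i_ms
    osc = step_ensemble(state.oscillators, params.oscillators,
                        max(state.e, 0.0), dt_ms)
    return MassState(e=e_new, i=i_new, oscillators=osc)


def run_mass_model(params: MassParams | None = None, duration_ms: float = 4000.0,
                   dt_ms: float = 0.01, stim_series=None,
                   record_every: int = 10):
    """Integrate the mass model; returns a dict of recorded series.

    ``stim_series`` is an optional per-step additive input to the excitatory
    mass.  Recorded at ``record_every``-step intervals (0.1 ms with the
    defaults): times_ms, e, i, theta_amplitude, theta_phase, theta_drive
    (normalized to [0, 1]).
    """
    params = params or MassParams()
    n_steps = int(round(duration_ms / dt_ms))
    state = init_mass_state(params)
    n_rec = n_steps // record_every
    out = {k: np.empty(n_rec) for k in
           ("times_ms", "e", "i", "theta_amplitude", "theta_phase",
            "theta_drive")}
    r = 0
    for k in range(n_steps):
        stim = 0.0 if stim_series is None else float(stim_series[k])
        state = step_mass_model(state, params, stim_e=stim, dt_ms=dt_ms)
        if k % record_every == record_every - 1 and r < n_rec:
            op = order_parameter(state.oscillators)
            out["times_ms"][r] = (k + 1) * dt_ms
            out["e"][r] = state.e
            out["i"][r] = state.i
            out["theta_amplitude"][r] = op.amplitude
            out["theta_phase"][r] = op.phase_rad
            out["theta_drive"][r] = (op.amplitude * np.cos(op.phase_rad)
                                     + 1.0) / 2.0
            r += 1
    return out
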