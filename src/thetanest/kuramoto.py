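"""Medial-septum theta generator: coupled Kuramoto phase oscillators with phase reset.

The medial septum contains pacemaker neurons whose collective activity imposes
the hippocampal theta rhythm.  Here the whole septal assembly is abstracted as
``N`` coupled phase oscillators

    dθ_i/dt = ω_i + (k/N) Σ_j sin(θ_j − θ_i) + G_reset · X(t) · Z(θ_i)

where ``ω_i`` are natural frequencies drawn from a normal distribution around a
center frequency, ``k/N`` is the synchronization ratio, ``X(t)`` is the
instantaneous firing rate of the CA1 excitatory population (the hippocampo-septal
feedback through the fornix) and ``Z`` is a biphasic phase-response function that
mediates theta phase reset.

The collective output is summarized by the complex order parameter
``r = (1/N) Σ e^{jθ_i}``: its modulus ``A`` measures synchrony, its argument
``φ`` is the ensemble phase.  The theta drive delivered to the entorhinal
cortex is a rectified cosine ``I_θ = G_θ (A cos φ + 1)/2``, non-negative and
bounded by the gain ``G_θ`` (nA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OscillatorEnsembleParams",
    "OscillatorEnsembleState",
    "ThetaDriveSample",
    "init_ensemble",
    "step_ensemble",
    "order_parameter",
    "theta_drive",
    "phase_response_fn",
    "wrap_phase",
]

TWO_PI = 2.0 * np.pi


def wrap_phase(theta):
    """Wrap angles to the principal interval (−π, π]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.angle(np.exp(1j * theta))
    # np.angle returns [-pi, pi]; map exactly -pi to +pi for the half-open convention
    if wrapped.ndim == 0:
        return float(np.pi if wrapped == -np.pi else wrapped)
    wrapped[wrapped == -np.pi] = np.pi
    return wrapped


@dataclass(frozen=True)
class OscillatorEnsembleParams:
    """Parameters of the septal oscillator ensemble.

    Defaults are the model's reference parameterization: 250 oscillators at
    6 ± 0.5 Hz, synchronization ratio k/N = 15, reset gain 4, theta peak at
    phase 0, firing-rate kernel time constant 10 ms.
    """

    n_oscillators: int = 250
    center_frequency_hz: float = 6.0
    frequency_sd_hz: float = 0.5
    sync_ratio: float = 15.0          # k/N, in rad/s per unit order parameter
    reset_gain: float = 4.0           # G_reset, scales the CA1 feedback X(t)
    peak_phase_rad: float = 0.0       # phase at which the theta drive peaks
    phase_offset_rad: float = 0.0     # offset of the reset zero from the peak
    theta_gain_na: float = 0.2        # G_theta, maximal drive current (nA)
    rate_time_constant_ms: float = 10.0  # tau_FR of the feedback rate kernel
    seed: int = 0

    def __post_init__(self):
        if self.n_oscillators < 1:
            raise ValueError("n_oscillators must be >= 1")
        if self.frequency_sd_hz < 0:
            raise ValueError("frequency_sd_hz must be >= 0")
        if self.rate_time_constant_ms <= 0:
            raise ValueError("rate_time_constant_ms must be > 0")
        if self.theta_gain_na < 0:
            raise ValueError("theta_gain_na must be >= 0")


@dataclass
class OscillatorEnsembleState:
    """Phases (rad, wrapped to (−π, π]) and natural frequencies (rad/s)."""

    phases_rad: np.ndarray
    natural_freqs_rad_s: np.ndarray

    def __post_init__(self):
        self.phases_rad = np.asarray(self.phases_rad, dtype=float)
        self.natural_freqs_rad_s = np.asarray(self.natural_freqs_rad_s, dtype=float)
        if self.phases_rad.shape != self.natural_freqs_rad_s.shape:
            raise ValueError("phases and natural frequencies must have equal length")


@dataclass(frozen=True)
class ThetaDriveSample:
    """One sample of the collective theta state: synchrony amplitude A in
    [0, 1], ensemble phase φ in (−π, π], and the rectified-cosine drive (nA)."""

    amplitude: float
    phase_rad: float
    drive_current_na: float = 0.0


def init_ensemble(params: OscillatorEnsembleParams) -> OscillatorEnsembleState:
    """Draw natural frequencies N(f0, σ²) (converted to rad/s) and uniform
    initial phases on the circle, reproducibly from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    freqs_hz = rng.normal(params.center_frequency_hz, params.frequency_sd_hz,
                          size=params.n_oscillators)
    phases = rng.uniform(-np.pi, np.pi, size=params.n_oscillators)
    return OscillatorEnsembleState(
        phases_rad=phases,
        natural_freqs_rad_s=TWO_PI * freqs_hz,
    )


def phase_response_fn(phase_rad, peak_phase_rad: float = 0.0,
                      phase_offset_rad: float = 0.0):
    """Biphasic phase-response function Z(θ) = −sin(θ − (θ_peak + φ_offset)).

    With the defaults (peak at 0, no offset) Z is positive on the ascending
    slope (−π, 0) — a perturbation advances the rhythm toward the peak — and
    negative on the descending slope (0, π), delaying it.
    """
    return -np.sin(np.asarray(phase_rad, dtype=float)
                   - (peak_phase_rad + phase_offset_rad))


def order_parameter(state: OscillatorEnsembleState) -> ThetaDriveSample:
    """Synchrony amplitude and ensemble phase from the complex mean of phases."""
    if state.phases_rad.size == 0:
        raise ValueError("order parameter undefined for an empty ensemble")
    r = np.exp(1j * state.phases_rad).mean()
    return ThetaDriveSample(amplitude=float(np.abs(r)), phase_rad=float(np.angle(r)))


def theta_drive(sample: ThetaDriveSample, theta_gain_na: float) -> float:
    """Rectified-cosine theta drive I_θ = G_θ (A cos φ + 1)/2, in [0, G_θ] nA."""
    if theta_gain_na < 0:
        raise ValueError("theta gain must be >= 0")
    return theta_gain_na * (sample.amplitude * np.cos(sample.phase_rad) + 1.0) / 2.0


def step_ensemble(state: OscillatorEnsembleState,
                  params: OscillatorEnsembleParams,
                  ca1_rate: float,
                  dt_ms: float) -> OscillatorEnsembleState:
    """Advance every phase one explicit-Euler step of length ``dt_ms``.

    Uses the mean-field identity (k/N) Σ_j sin(θ_j − θ_i) = k·A·sin(φ − θ_i),
    which is exact, so the cost is O(N) per step.  ``ca1_rate`` is X(t), the
    instantaneous CA1 excitatory firing rate in 1/s.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    if ca1_rate < 0:
        raise ValueError("ca1_rate must be >= 0")
    theta = state.phases_rad
    n = theta.size
    r = np.exp(1j * theta).mean()
    amp, psi = np.abs(r), np.angle(r)
    # (k/N) sum_j sin(theta_j - theta_i) = (k/N) * N * A * sin(phi - theta_i);
    # sync_ratio stores k/N, so the total coupling scales with N
    dtheta = (state.natural_freqs_rad_s
              + params.sync_ratio * n * amp * np.sin(psi - theta)
              + params.reset_gain * ca1_rate
              * phase_response_fn(theta, params.peak_phase_rad,
                                  params.phase_offset_rad))
    new = wrap_phase(theta + dtheta * (dt_ms * 1e-3))
    return OscillatorEnsembleState(phases_rad=new,
                                   natural_freqs_rad_s=state.natural_freqs_rad_s)
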