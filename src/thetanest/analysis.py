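"""Oscillation-analysis stack for simulated population activity.

Implements the measures used to characterize theta-nested gamma activity:

* instantaneous population firing rates (sliding rectangular windows);
* Welch power spectral densities with Simpson-rule band power;
* short-time Fourier spectrograms (Hann taper);
* theta-gamma phase-amplitude coupling via the modulation index (MI): the
  Kullback–Leibler divergence between the phase-binned mean-amplitude
  distribution and the uniform distribution, normalized to [0, 1];
* comodulograms over overlapping phase/amplitude frequency bands, with
  uniform noise injected into the rate signals first — band-pass filtering a
  simulated rate that lacks power in narrow bands yields a flat signal and a
  spuriously high MI, and the injected noise suppresses that artifact;
* preferred-phase histograms (amplitude-by-phase per gamma band);
* phase response curves (PRC): the theta phase shift produced by a single
  pulse as a function of the phase at which it is delivered, estimated from
  paired stimulated/unstimulated runs.

Band-pass filtering uses zero-phase FIR filters (window method) with
transition widths of 20% of the band edges; phases/amplitudes come from the
Hilbert transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.integrate import simpson

from .kuramoto import (OscillatorEnsembleParams, init_ensemble, order_parameter,
                       step_ensemble, wrap_phase)

__all__ = [
    "RateSeries",
    "PACResult",
    "PhaseResponseCurve",
    "binned_rate",
    "psd_and_bandpower",
    "spectrogram",
    "bandpass",
    "modulation_index",
    "comodulogram",
    "preferred_phase",
    "compute_prc",
    "ensemble_prc",
    "detect_bursts",
    "fade_time_ms",
    "spectral_peak_hz",
    "gamma_ridge_hz",
]


# ---------------------------------------------------------------------------
# firing rates
# ---------------------------------------------------------------------------

@dataclass
class RateSeries:
    """Instantaneous population firing rate on a sliding-window grid."""

    times_ms: np.ndarray
    rate_hz: np.ndarray
    bin_ms: float
    overlap: float

    @property
    def fs(self) -> float:
        """Sample rate of the series (Hz)."""
        return 1000.0 / (self.bin_ms * (1.0 - self.overlap))


def binned_rate(spike_times_ms, n_neurons: int, duration_ms: float,
                bin_ms: float = 5.0, overlap: float = 0.9) -> RateSeries:
    """Sliding-window rate: spike count / (bin width × population size).

    Consecutive windows are spaced ``bin·(1−overlap)`` (0.5 ms with the
    defaults).  Window centers are reported as times.
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be > 0")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    step = bin_ms * (1.0 - overlap)
    ratio = bin_ms / step
    n_sub = int(round(ratio))
    if abs(ratio - n_sub) > 1e-9:
        raise ValueError("bin width must be an integer multiple of the step")
    edges = np.arange(0.0, duration_ms + step / 2, step)
    counts = np.histogram(np.asarray(spike_times_ms, dtype=float), edges)[0]
    window_counts = np.convolve(counts, np.ones(n_sub), mode="valid")
    starts = edges[: window_counts.size]
    rate = window_counts / (bin_ms * 1e-3 * n_neurons)
    return RateSeries(times_ms=starts + bin_ms / 2, rate_hz=rate,
                      bin_ms=bin_ms, overlap=overlap)


# ---------------------------------------------------------------------------
# spectral estimates
# ---------------------------------------------------------------------------

def psd_and_bandpower(x, fs: float, window_s: float = 1.0,
                      overlap: float = 0.9, band=None):
    """Welch PSD (1 s windows, 90% overlap by default → 1 Hz resolution)
    and, if ``band=(lo, hi)`` is given, the Simpson-rule band power."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise ValueError("signal shorter than one Welch window")
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg,
                              noverlap=int(round(overlap * nperseg)))
    if band is None:
        return freqs, psd, None
    lo, hi = band
    if not (0 <= lo < hi <= fs / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2}) range")
    m = (freqs >= lo) & (freqs <= hi)
    if m.sum() < 2:
        raise ValueError("band narrower than the frequency resolution")
    return freqs, psd, float(simpson(psd[m], x=freqs[m]))


def spectrogram(x, fs: float, window_ms: float = 100.0, overlap: float = 0.99):
    """Hann-tapered STFT power (100 ms windows → 10 Hz resolution).

    Returns (freqs_hz, times_s, power).
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_ms * 1e-3 * fs))
    if x.size < nperseg:
        raise ValueError("signal shorter than one spectrogram window")
    freqs, times, sxx = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), mode="psd")
    return freqs, times, sxx


# ---------------------------------------------------------------------------
# event-level measures on population rates
# ---------------------------------------------------------------------------

def detect_bursts(rate: RateSeries, threshold_hz: float = 5.0,
                  min_gap_ms: float = 50.0):
    """Onset times of contiguous suprathreshold excursions of the rate.

    Excursions separated by less than ``min_gap_ms`` are merged into one
    burst.  Returns onset times in ms.
    """
    onsets = []
    in_burst = False
    prev_off = -np.inf
    for t, above in zip(rate.times_ms, rate.rate_hz > threshold_hz):
        if above and not in_burst:
            if onsets and t - prev_off < min_gap_ms:
                in_burst = True
                continue
            onsets.append(float(t))
            in_burst = True
        elif not above and in_burst:
            prev_off = t
            in_burst = False
    return onsets


def fade_time_ms(rate: RateSeries, onset_ms: float,
                 threshold_hz: float = 2.0, hold_ms: float = 200.0):
    """Time from ``onset_ms`` until the rate drops below ``threshold_hz``
    and stays there for ``hold_ms``; None if it never does."""
    sel = rate.times_ms >= onset_ms
    t = rate.times_ms[sel]
    below = rate.rate_hz[sel] < threshold_hz
    if t.size < 2:
        return None
    need = max(1, int(round(hold_ms / (t[1] - t[0]))))
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= need:
            return float(t[i - need + 1] - onset_ms)
    return None


def spectral_peak_hz(x, fs: float, band=(1.0, 10.0), **welch_kwargs) -> float:
    """Frequency of the Welch-PSD maximum within a band."""
    x = np.asarray(x, dtype=float)
    f, p, _ = psd_and_bandpower(x - x.mean(), fs, **welch_kwargs)
    sel = (f >= band[0]) & (f <= band[1])
    return float(f[sel][np.argmax(p[sel])])


def gamma_ridge_hz(x, fs: float, theta_phase=None, phase_dt_ms: float = 0.1,
                   band=(30.0, 120.0), peak_halfwidth_rad: float = np.pi / 4,
                   window_ms: float = 100.0, overlap: float = 0.99) -> float:
    """Frequency of maximal mean spectrogram power in a band.

    If a theta phase series is supplied, only spectrogram columns within
    ``peak_halfwidth_rad`` of the theta peak (phase 0) enter the average —
    the gamma ridge during theta-peak epochs.
    """
    x = np.asarray(x, dtype=float)
    f, ts, sxx = spectrogram(x - x.mean(), fs, window_ms=window_ms,
                             overlap=overlap)
    cols = np.ones(ts.size, dtype=bool)
    if theta_phase is not None:
        idx = np.clip((ts * 1000.0 / phase_dt_ms).astype(int), 0,
                      len(theta_phase) - 1)
        near_peak = np.abs(np.asarray(theta_phase)[idx]) < peak_halfwidth_rad
        if near_peak.sum() >= 5:
            cols = near_peak
    sel = (f >= band[0]) & (f <= band[1])
    return float(f[sel][np.argmax(sxx[np.ix_(sel, cols)].mean(axis=1))])


# ---------------------------------------------------------------------------
# phase-amplitude coupling
# ---------------------------------------------------------------------------

def bandpass(x, fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase FIR band-pass with 20%-of-edge transition widths."""
    x = np.asarray(x, dtype=float)
    numtaps = int(round(3.0 * fs / max(lo * 0.2, 0.2)))
    # filtfilt pads by 3*numtaps samples: keep that below the signal length
    numtaps = min(numtaps, max((x.size - 2) // 3, 3))
    if numtaps % 2 == 0:
        numtaps -= 1
    taps = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    return signal.filtfilt(taps, [1.0], x)


def _maybe_decimate(x, fs, f_max):
    """Polyphase-resample to ~4× the highest analysis frequency.

    PAC filtering cost scales with fs²; the narrow-band filters only need
    modest headroom above the amplitude band, and resampling is linear so
    MI properties (scaling invariance in particular) are unaffected.
    """
    target = 4.0 * f_max
    down = int(fs // target)
    if down > 1:
        return signal.resample_poly(x, 1, down), fs / down
    return x, fs


def _phase_amplitude(x, fs, phase_band, amp_band):
    x, fs = _maybe_decimate(x, fs, amp_band[1])
    xp = bandpass(x, fs, *phase_band)
    xa = bandpass(x, fs, *amp_band)
    return np.angle(signal.hilbert(xp)), np.abs(signal.hilbert(xa))


def _amp_by_phase(phase, amp, n_bins):
    idx = np.clip(((phase + np.pi) / (2 * np.pi) * n_bins).astype(int),
                  0, n_bins - 1)
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    counts = np.maximum(np.bincount(idx, minlength=n_bins), 1)
    return sums / counts


def _mi_from_hist(mean_amp):
    """Normalized KL divergence of the amplitude-by-phase histogram."""
    n = mean_amp.size
    total = mean_amp.sum()
    if total <= 0:
        return 0.0
    p = mean_amp / total
    nz = p > 0
    return float((np.log(n) + (p[nz] * np.log(p[nz])).sum()) / np.log(n))


@dataclass
class PACResult:
    """Modulation index and its amplitude-by-phase histogram."""

    modulation_index: float
    phase_band_hz: tuple
    amp_band_hz: tuple
    n_phase_bins: int
    amp_by_phase: np.ndarray
    phase_bin_centers: np.ndarray
    degenerate: bool = False


def modulation_index(x, fs: float, phase_band=(3.0, 9.0),
                     amp_band=(40.0, 80.0), n_bins: int = 72) -> PACResult:
    """Tort modulation index with 5° phase bins.

    Band-pass both bands, extract Hilbert phase/amplitude, average the
    amplitude per phase bin, and normalize the KL divergence to the uniform
    distribution by log(n_bins) so MI ∈ [0, 1].  A zero-amplitude signal is
    flagged degenerate and reported as MI = 0.
    """
    x = np.asarray(x, dtype=float)
    centers = -np.pi + (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
    if np.allclose(x, x.flat[0] if x.size else 0.0):
        return PACResult(0.0, tuple(phase_band), tuple(amp_band), n_bins,
                         np.zeros(n_bins), centers, degenerate=True)
    phase, amp = _phase_amplitude(x, fs, phase_band, amp_band)
    if not np.any(amp > 0):
        return PACResult(0.0, tuple(phase_band), tuple(amp_band), n_bins,
                         np.zeros(n_bins), centers, degenerate=True)
    hist = _amp_by_phase(phase, amp, n_bins)
    return PACResult(_mi_from_hist(hist), tuple(phase_band), tuple(amp_band),
                     n_bins, hist, centers)


def _overlapping_bands(lo, hi, width, overlap):
    step = width * (1.0 - overlap)
    starts = np.arange(lo, hi - width + step / 2, step)
    return [(s, s + width) for s in starts]


def comodulogram(x, fs: float, phase_range=(2.0, 10.0), phase_width: float = 1.0,
                 phase_overlap: float = 0.8, amp_range=(20.0, 100.0),
                 amp_width: float = 10.0, amp_overlap: float = 0.9,
                 n_bins: int = 72, noise_fraction: float = 0.2, seed: int = 0):
    """MI matrix over overlapping (phase band × amplitude band) pairs.

    Uniform noise with amplitude ``noise_fraction × max(x)`` is added before
    filtering (``noise_fraction=0`` reduces to the plain MI); the seed is
    returned alongside the matrix for reproducibility.

    Returns (phase_centers, amp_centers, mi_matrix, seed).
    """
    x = np.asarray(x, dtype=float)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.uniform(0.0, noise_fraction * np.abs(x).max() + 1e-30,
                            size=x.shape)
    x, fs = _maybe_decimate(x, fs, amp_range[1])
    p_bands = _overlapping_bands(*phase_range, phase_width, phase_overlap)
    a_bands = _overlapping_bands(*amp_range, amp_width, amp_overlap)
    phases = [np.angle(signal.hilbert(bandpass(x, fs, *b))) for b in p_bands]
    amps = [np.abs(signal.hilbert(bandpass(x, fs, *b))) for b in a_bands]
    mi = np.empty((len(p_bands), len(a_bands)))
    for i, ph in enumerate(phases):
        for j, am in enumerate(amps):
            mi[i, j] = _mi_from_hist(_amp_by_phase(ph, am, n_bins))
    return (np.array([(a + b) / 2 for a, b in p_bands]),
            np.array([(a + b) / 2 for a, b in a_bands]), mi, seed)


def preferred_phase(x, fs: float, phase_band=(3.0, 9.0),
                    amp_range=(20.0, 100.0), amp_width: float = 10.0,
                    amp_overlap: float = 0.9, n_bins: int = 72):
    """Amplitude-by-phase histograms per narrow gamma band (polar-plot data).

    Returns (band_centers, phase_bin_centers, amp_by_phase matrix,
    preferred_phase per band = argmax of the histogram).
    """
    x = np.asarray(x, dtype=float)
    x, fs = _maybe_decimate(x, fs, amp_range[1])
    xp = bandpass(x, fs, *phase_band)
    phase = np.angle(signal.hilbert(xp))
    bands = _overlapping_bands(*amp_range, amp_width, amp_overlap)
    centers = -np.pi + (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
    hists = np.empty((len(bands), n_bins))
    for i, b in enumerate(bands):
        amp = np.abs(signal.hilbert(bandpass(x, fs, *b)))
        hists[i] = _amp_by_phase(phase, amp, n_bins)
    pref = centers[np.argmax(hists, axis=1)]
    return (np.array([(a + b) / 2 for a, b in bands]), centers, hists, pref)


# ---------------------------------------------------------------------------
# phase response curves
# ---------------------------------------------------------------------------

@dataclass
class PhaseResponseCurve:
    """Δφ (advance > 0, delay < 0) per stimulation phase and amplitude."""

    phases_rad: np.ndarray
    amplitudes: np.ndarray
    delta_phi: np.ndarray       # shape (n_amplitudes, n_phases)
    lag_ms: float = 2.5


def compute_prc(model, amplitudes_na, phases_rad=None, lag_ms: float = 2.5,
                arming_ms: float = 500.0, duration_ms: float | None = None,
                pulse_width_ms: float = 1.0, target_area: str = "CA1",
                seed: int = 0) -> PhaseResponseCurve:
    """PRC of the closed-loop model by paired stimulated/unstimulated runs.

    One theta cycle is split into π/8-wide intervals (default grid); for
    each phase and amplitude a single pulse is delivered at the first
    crossing of that phase after ``arming_ms``, and Δφ is the wrapped
    difference between the stimulated and unstimulated theta phase
    ``lag_ms`` after pulse onset.
    """
    from .network import StimulusProtocol, make_stimulus

    if phases_rad is None:
        phases_rad = -np.pi + np.pi / 8 * (np.arange(16) + 0.5)
    phases_rad = np.asarray(phases_rad, dtype=float)
    amplitudes_na = np.atleast_1d(np.asarray(amplitudes_na, dtype=float))
    ref = model.run(duration_ms=duration_ms, seed=seed)
    dt = ref.dt_ms
    lag_steps = int(round(lag_ms / dt))
    dphi = np.empty((amplitudes_na.size, phases_rad.size))
    for j, ph in enumerate(phases_rad):
        proto = StimulusProtocol(target_area=target_area, amplitude_na=1.0,
                                 pulse_width_ms=pulse_width_ms, mode="phase",
                                 phase_rad=float(ph), arming_ms=arming_ms)
        stim_unit = make_stimulus(proto, ref.n_steps, dt,
                                  theta_phase_series=ref.theta_phase)
        onset = int(np.flatnonzero(stim_unit)[0])
        probe = min(onset + lag_steps, ref.n_steps - 1)
        for i, amp in enumerate(amplitudes_na):
            tr = model.run(duration_ms=duration_ms, seed=seed,
                           stim_series=stim_unit * amp,
                           protocol=StimulusProtocol(
                               target_area=target_area, amplitude_na=amp,
                               mode="times", times_ms=()))
            dphi[i, j] = wrap_phase(tr.theta_phase[probe]
                                    - ref.theta_phase[probe])
    return PhaseResponseCurve(phases_rad=phases_rad, amplitudes=amplitudes_na,
                              delta_phi=dphi, lag_ms=lag_ms)


def ensemble_prc(params: OscillatorEnsembleParams, amplitudes,
                 phases_rad=None, lag_ms: float = 2.5, dt_ms: float = 0.1,
                 pulse_width_ms: float = 1.0, settle_ms: float = 2000.0):
    """PRC of the isolated oscillator ensemble under a rate pulse X(t).

    A direct probe of the reset pathway without the spiking network:
    ``amplitudes`` are the magnitudes of a rectangular X(t) pulse (1/s).
    For small perturbations Δφ ≈ G_reset·X·w·Z(φ) — the −sin shape of the
    phase-response function.
    """
    if phases_rad is None:
        phases_rad = -np.pi + np.pi / 8 * (np.arange(16) + 0.5)
    phases_rad = np.asarray(phases_rad, dtype=float)
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))

    state0 = init_ensemble(params)
    n_settle = int(round(settle_ms / dt_ms))
    for _ in range(n_settle):
        state0 = step_ensemble(state0, params, 0.0, dt_ms)

    width_steps = max(1, int(round(pulse_width_ms / dt_ms)))
    lag_steps = int(round(lag_ms / dt_ms))
    period_steps = int(round(1000.0 / params.center_frequency_hz / dt_ms))
    dphi = np.empty((amplitudes.size, phases_rad.size))
    for j, target in enumerate(phases_rad):
        # advance the settled ensemble to the first crossing of the target
        st = state0
        prev = wrap_phase(order_parameter(st).phase_rad - target)
        onset_state = None
        for _ in range(3 * period_steps):
            st = step_ensemble(st, params, 0.0, dt_ms)
            d = wrap_phase(order_parameter(st).phase_rad - target)
            if prev <= 0.0 <= d and (d - prev) < np.pi:
                onset_state = st
                break
            prev = d
        if onset_state is None:
            raise RuntimeError(f"phase {target:.2f} rad never crossed")
        for i, amp in enumerate(amplitudes):
            stim = onset_state
            free = onset_state
            for k in range(lag_steps):
                x = amp if k < width_steps else 0.0
                stim = step_ensemble(stim, params, x, dt_ms)
                free = step_ensemble(free, params, 0.0, dt_ms)
            dphi[i, j] = wrap_phase(order_parameter(stim).phase_rad
                                    - order_parameter(free).phase_rad)
    return PhaseResponseCurve(phases_rad=phases_rad, amplitudes=amplitudes,
                              delta_phi=dphi, lag_ms=lag_ms)
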