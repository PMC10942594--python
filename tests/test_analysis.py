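"""Oscillation analysis: rates, spectra, PAC metrics, phase response."""

import numpy as np
import pytest

from thetanest import analysis as an
from thetanest.fixtures import make_pac_signal
from thetanest.kuramoto import OscillatorEnsembleParams, phase_response_fn


class TestBinnedRate:
    def test_no_spikes_gives_zero_series(self):
        rs = an.binned_rate([], 100, 1000.0)
        assert np.all(rs.rate_hz == 0)
        assert rs.fs == pytest.approx(2000.0)

    def test_single_spike_rate_value(self):
        """One spike, 100 neurons, 5 ms bin -> 2 Hz in covering windows."""
        rs = an.binned_rate([500.0], 100, 1000.0)
        assert rs.rate_hz.max() == pytest.approx(1 / (0.005 * 100))
        covering = np.abs(rs.times_ms - 500.0) <= 2.5
        assert np.all(rs.rate_hz[covering & (np.abs(rs.times_ms - 500.0) < 2.0)]
                      > 0)

    def test_total_spike_mass_conserved(self):
        """Each spike is counted by exactly bin/step covering windows, so
        sum(rate)*bin_s*N / (bin/step) recovers the spike count."""
        rng = np.random.default_rng(1)
        spikes = rng.uniform(50.0, 950.0, size=400)
        rs = an.binned_rate(spikes, 37, 1000.0, bin_ms=5.0, overlap=0.9)
        windows_per_spike = 10
        recovered = rs.rate_hz.sum() * 0.005 * 37 / windows_per_spike
        assert recovered == pytest.approx(len(spikes), rel=1e-6)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            an.binned_rate([], 10, 100.0, bin_ms=0)
        with pytest.raises(ValueError):
            an.binned_rate([], 10, 100.0, overlap=1.0)


class TestSpectral:
    def test_pure_sinusoid_peak_location(self):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 4.0 * t)
        f, p, _ = an.psd_and_bandpower(x, fs)
        assert f[np.argmax(p)] == pytest.approx(4.0)
        assert f[1] - f[0] == pytest.approx(1.0)  # 1 s window -> 1 Hz bins

    def test_band_power_of_white_noise_scales_with_bandwidth(self):
        rng = np.random.default_rng(0)
        fs = 1000.0
        x = rng.normal(size=int(60 * fs))
        _, _, p1 = an.psd_and_bandpower(x, fs, band=(100, 150))
        _, _, p2 = an.psd_and_bandpower(x, fs, band=(100, 200))
        assert p2 / p1 == pytest.approx(2.0, rel=0.15)

    def test_parseval_total_power_matches_variance(self):
        rng = np.random.default_rng(3)
        fs = 1000.0
        x = rng.normal(size=int(120 * fs))
        f, p, total = an.psd_and_bandpower(x, fs, band=(0.0, fs / 2))
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_band_outside_nyquist_rejected(self):
        x = np.random.default_rng(0).normal(size=4000)
        with pytest.raises(ValueError):
            an.psd_and_bandpower(x, 1000.0, band=(100, 600))

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            an.psd_and_bandpower(np.ones(100), 1000.0)

    def test_spectrogram_tracks_stationary_tone(self):
        fs = 1000.0
        t = np.arange(int(5 * fs)) / fs
        x = np.sin(2 * np.pi * 60.0 * t)
        f, ts, sxx = an.spectrogram(x, fs)
        ridge = f[np.argmax(sxx, axis=0)]
        assert np.all(np.abs(ridge - 60.0) <= 10.0)
        assert f[1] - f[0] == pytest.approx(10.0)  # 100 ms window -> 10 Hz

    def test_spectrogram_tracks_chirp(self):
        from scipy.signal import chirp
        fs = 1000.0
        t = np.arange(int(8 * fs)) / fs
        x = chirp(t, f0=30.0, f1=110.0, t1=t[-1], method="linear")
        f, ts, sxx = an.spectrogram(x, fs)
        ridge = f[np.argmax(sxx, axis=0)]
        inst = 30.0 + (110.0 - 30.0) * ts / t[-1]
        assert np.mean(np.abs(ridge - inst)) < 8.0


class TestModulationIndex:
    def test_uniform_histogram_gives_zero(self):
        assert an._mi_from_hist(np.ones(72)) == pytest.approx(0.0)

    def test_all_mass_in_one_bin_gives_one(self):
        h = np.zeros(72)
        h[10] = 3.0
        assert an._mi_from_hist(h) == pytest.approx(1.0)

    def test_degenerate_signal_flagged_zero(self):
        res = an.modulation_index(np.zeros(20000), 1000.0)
        assert res.modulation_index == 0.0 and res.degenerate

    def test_coupled_exceeds_uncoupled_control(self, pac_signal_pair):
        coupled, flat = pac_signal_pair
        mi_c = an.modulation_index(coupled, 1000.0).modulation_index
        mi_f = an.modulation_index(flat, 1000.0).modulation_index
        assert 0.0 <= mi_f < mi_c <= 1.0
        assert mi_c > 3 * mi_f

    def test_amplitude_scaling_invariance(self, pac_signal_pair):
        coupled, _ = pac_signal_pair
        a = an.modulation_index(coupled, 1000.0).modulation_index
        b = an.modulation_index(coupled * 37.5, 1000.0).modulation_index
        assert a == pytest.approx(b, rel=1e-9)

    def test_histogram_peaks_at_coupling_phase(self):
        """Gamma amplitude proportional to (1+cos theta): the histogram's
        maximum sits near phase 0 (the theta peak)."""
        _, x = make_pac_signal(duration_s=30.0, depth=1.0, noise_sd=0.02,
                               seed=2)
        res = an.modulation_index(x, 1000.0)
        peak_phase = res.phase_bin_centers[np.argmax(res.amp_by_phase)]
        assert abs(peak_phase) < np.pi / 6


class TestComodulogram:
    def test_maximum_at_constructed_bands(self):
        _, x = make_pac_signal(duration_s=25.0, f_phase_hz=5.0,
                               f_amp_hz=60.0, depth=1.0, noise_sd=0.05,
                               seed=8)
        pc, ac, mi, _ = an.comodulogram(x, 1000.0, seed=1)
        i, j = np.unravel_index(np.argmax(mi), mi.shape)
        assert abs(pc[i] - 5.0) <= 1.0
        assert 55.0 <= ac[j] <= 65.0

    def test_zero_noise_fraction_reduces_to_plain_mi(self, pac_signal_pair):
        coupled, _ = pac_signal_pair
        a = an.comodulogram(coupled, 1000.0, noise_fraction=0.0, seed=3)[2]
        b = an.comodulogram(coupled, 1000.0, noise_fraction=0.0, seed=99)[2]
        assert np.array_equal(a, b)  # seed irrelevant without noise

    def test_noise_injection_suppresses_flat_signal_artifact(self):
        """Band-passing a spectrally empty signal yields a spuriously high
        MI; the injected uniform noise removes the artifact."""
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 6.0 * t)   # no gamma content at all
        no_fix = an.comodulogram(x, fs, noise_fraction=0.0, seed=0)[2]
        fixed = an.comodulogram(x, fs, noise_fraction=0.2, seed=0)[2]
        assert no_fix.max() > 10 * fixed.max()
        assert fixed.max() < 0.05


class TestPreferredPhase:
    @pytest.mark.parametrize("shift,expected", [(0.0, 0.0),
                                                (np.pi / 2, np.pi / 2)])
    def test_preferred_phase_follows_modulation(self, shift, expected):
        fs = 1000.0
        t = np.arange(int(25 * fs)) / fs
        slow_phase = 2 * np.pi * 6.0 * t
        env = (1 + np.cos(slow_phase - shift)) / 2
        x = env * np.cos(2 * np.pi * 60.0 * t) + 0.5 * np.cos(slow_phase)
        bands, centers, hists, pref = an.preferred_phase(x, fs)
        band = np.argmin(np.abs(bands - 60.0))
        assert abs(an.wrap_phase(pref[band] - expected)) < np.pi / 8


class TestClosedLoopPhaseResponse:
    def test_paired_run_prc_advance_on_ascending_slope(self):
        """compute_prc on the closed-loop model: a pulse on the ascending
        slope of theta ignites CA1, whose rate feedback advances the
        ensemble phase; with the reset pathway off the shift vanishes."""
        from thetanest.network import build_network
        from thetanest.reference import SWITCHABLE_DRIVE_NA, reference_config

        model = build_network(reference_config(
            theta_gain_na=SWITCHABLE_DRIVE_NA, duration_ms=3000.0))
        curve = an.compute_prc(model, amplitudes_na=[10.0],
                               phases_rad=[-np.pi / 2], lag_ms=2.5,
                               arming_ms=1500.0, seed=3)
        assert curve.delta_phi.shape == (1, 1)
        assert curve.delta_phi[0, 0] > 0.0
        no_reset = model.with_updates(reset_on=False)
        flat = an.compute_prc(no_reset, amplitudes_na=[10.0],
                              phases_rad=[-np.pi / 2], lag_ms=2.5,
                              arming_ms=1500.0, seed=3)
        assert abs(flat.delta_phi[0, 0]) < abs(curve.delta_phi[0, 0])


class TestEnsemblePhaseResponse:
    def test_no_reset_gain_means_no_phase_shift(self):
        p = OscillatorEnsembleParams(n_oscillators=30, reset_gain=0.0, seed=1)
        curve = an.ensemble_prc(p, amplitudes=[50.0], settle_ms=500.0,
                                phases_rad=np.linspace(-3, 3, 5))
        assert np.allclose(curve.delta_phi, 0.0, atol=1e-6)

    def test_matches_minus_sine_shape_in_small_perturbation_limit(self):
        """For a short weak pulse, delta phi ~ G*X*w*Z(phase): the biphasic
        -sin of the phase-response function."""
        p = OscillatorEnsembleParams(n_oscillators=50, reset_gain=4.0, seed=2)
        phases = np.linspace(-np.pi + 0.2, np.pi - 0.2, 9)
        curve = an.ensemble_prc(p, amplitudes=[20.0], phases_rad=phases,
                                settle_ms=1000.0, lag_ms=2.5)
        predicted = phase_response_fn(phases)
        measured = curve.delta_phi[0]
        scale = np.dot(measured, predicted) / np.dot(predicted, predicted)
        assert scale > 0
        resid = measured - scale * predicted
        assert np.sqrt(np.mean(resid ** 2)) < 0.25 * np.abs(measured).max()

    def test_advance_ascending_delay_descending_and_amplitude_monotone(self):
        p = OscillatorEnsembleParams(n_oscillators=50, reset_gain=4.0, seed=3)
        phases = np.array([-np.pi / 2, np.pi / 2])
        curve = an.ensemble_prc(p, amplitudes=[20.0, 60.0],
                                phases_rad=phases, settle_ms=1000.0)
        # ascending slope -> advance; descending -> delay
        assert np.all(curve.delta_phi[:, 0] > 0)
        assert np.all(curve.delta_phi[:, 1] < 0)
        # stronger pulses shift more
        assert np.all(np.abs(curve.delta_phi[1]) >= np.abs(curve.delta_phi[0]))
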