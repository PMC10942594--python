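"""Closed-loop assembly, stimulation protocols, rate feedback, engine."""

import numpy as np
import pytest

from thetanest.network import (NetworkConfig, StimulusProtocol,
                               build_ei_circuit, build_network,
                               firing_rate_feedback, make_stimulus)
from thetanest.network import ProtocolError, SimulationError
from thetanest.kuramoto import OscillatorEnsembleParams


class TestFiringRateFeedback:
    def test_exponential_decay_without_spikes(self):
        x = firing_rate_feedback([], 10, tau_fr_ms=10.0, dt_ms=0.1,
                                 n_steps=1000, x0=50.0)
        t = (np.arange(1000) + 1) * 0.1
        assert np.allclose(x, 50.0 * np.exp(-t / 10.0), rtol=1e-9)

    def test_single_spike_jump_amplitude(self):
        """One spike, N=1, tau=10 ms: instantaneous jump of 100 1/s."""
        x = firing_rate_feedback([0.0], 1, tau_fr_ms=10.0, dt_ms=0.1,
                                 n_steps=10)
        assert x[0] == pytest.approx(100.0, rel=1e-9)
        assert x[1] == pytest.approx(100.0 * np.exp(-0.1 / 10.0), rel=1e-9)

    def test_poisson_population_time_average_equals_rate(self):
        """Homogeneous Poisson spiking at f per neuron: mean X -> f."""
        rng = np.random.default_rng(0)
        f, n, dur_s = 20.0, 50, 30.0
        spikes = rng.uniform(0, dur_s * 1000, size=rng.poisson(f * n * dur_s))
        x = firing_rate_feedback(spikes, n, 10.0, 1.0, int(dur_s * 1000))
        # discrete decay with dt=1 ms biases the mean by dt/tau/(1-e^-dt/tau)
        expected = f * (1.0 / 10.0) / (1 - np.exp(-1.0 / 10.0))
        assert x[1000:].mean() == pytest.approx(expected, rel=0.03)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            firing_rate_feedback([], 1, 0.0, 0.1, 10)


class TestMakeStimulus:
    def test_explicit_times_pulse_window(self):
        proto = StimulusProtocol(amplitude_na=10.0, pulse_width_ms=1.0,
                                 mode="times", times_ms=(100.0,))
        s = make_stimulus(proto, 2000, 0.1)
        assert np.all(s[1000:1010] == 10.0)
        assert s[999] == 0.0 and s[1010] == 0.0
        assert np.count_nonzero(s) == 10

    def test_train_pulse_count_and_spacing(self):
        """6 Hz for 2 s -> 12 pulses spaced 166.7 ms."""
        proto = StimulusProtocol(amplitude_na=1.0, mode="train", train_hz=6.0,
                                 train_duration_ms=2000.0, arming_ms=0.0)
        s = make_stimulus(proto, 40000, 0.1)
        onsets = np.flatnonzero(np.diff((s > 0).astype(int)) == 1) + 1
        onsets = np.insert(onsets, 0, 0) if s[0] > 0 else onsets
        assert onsets.size == 12
        assert np.allclose(np.diff(onsets) * 0.1, 1000.0 / 6.0, atol=0.1)

    def test_phase_targeted_onset_at_crossing(self):
        t = np.arange(50000) * 0.1
        phase = np.angle(np.exp(1j * 2 * np.pi * 6.0 * t / 1000.0))
        proto = StimulusProtocol(amplitude_na=2.0, mode="phase",
                                 phase_rad=0.5, arming_ms=1000.0)
        s = make_stimulus(proto, 50000, 0.1, theta_phase_series=phase)
        onset = np.flatnonzero(s)[0]
        assert onset >= 10000
        assert abs(phase[onset] - 0.5) < 0.06

    def test_phase_never_reached_raises(self):
        phase = np.full(10000, -2.0)
        proto = StimulusProtocol(mode="phase", phase_rad=0.5)
        with pytest.raises(ProtocolError):
            make_stimulus(proto, 10000, 0.1, theta_phase_series=phase)

    def test_phase_mode_requires_phase_series(self):
        with pytest.raises(ProtocolError):
            make_stimulus(StimulusProtocol(mode="phase"), 100, 0.1)

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol(amplitude_na=np.inf)
        with pytest.raises(ValueError):
            StimulusProtocol(mode="banana")
        with pytest.raises(ValueError):
            StimulusProtocol(mode="train", train_hz=0.0)


class TestBuildAndRun:
    def test_structure_matches_block_diagram(self, tiny_loop_model):
        provs = set(np.unique(tiny_loop_model.graph.provenance))
        inter = {p.split(":")[1] for p in provs if p.startswith("inter")}
        assert inter == {"EC->DG", "EC->CA3", "EC->CA1", "DG->CA3",
                         "CA3->CA1", "CA1->EC"}
        assert tiny_loop_model.theta_area == tiny_loop_model.areas.index("EC")

    def test_reset_flag_changes_dynamics_not_wiring(self, tiny_loop_model):
        m2 = tiny_loop_model.with_updates(reset_on=False)
        assert np.array_equal(m2.post_idx, tiny_loop_model.post_idx)
        assert np.array_equal(m2.w_us, tiny_loop_model.w_us)

    def test_identical_seeds_identical_rasters(self, tiny_loop_model):
        a = tiny_loop_model.run(seed=5, duration_ms=400.0)
        b = tiny_loop_model.run(seed=5, duration_ms=400.0)
        assert np.array_equal(a.spike_times_ms, b.spike_times_ms)
        assert np.array_equal(a.spike_ids, b.spike_ids)
        assert np.array_equal(a.theta_phase, b.theta_phase)

    def test_different_seeds_differ(self, tiny_loop_model):
        a = tiny_loop_model.run(seed=5, duration_ms=400.0)
        b = tiny_loop_model.run(seed=6, duration_ms=400.0)
        assert not np.array_equal(a.spike_times_ms, b.spike_times_ms)

    def test_no_drive_no_noise_no_stim_is_silent(self):
        """Energy sanity: every spike needs a source."""
        cfg = NetworkConfig(
            counts={"CA1": (50, 5)}, seed=1, noise_on=False,
            duration_ms=500.0, z_extent_um=50.0, geometry_scale_xy=0.01,
            a_inter={},
            oscillator=OscillatorEnsembleParams(theta_gain_na=0.0))
        tr = build_network(cfg).run(seed=2)
        assert tr.spike_times_ms.size == 0

    def test_zero_theta_gain_keeps_excitatory_populations_silent(
            self, tiny_loop_model):
        m = tiny_loop_model.with_updates(
            oscillator=OscillatorEnsembleParams(theta_gain_na=0.0))
        tr = m.run(seed=3, duration_ms=1000.0)
        for a in m.areas:
            assert tr.mean_rate_hz(a, "E", 0, 1000.0) == 0.0

    def test_engine_matches_reference_single_neuron(self):
        """Engine trajectory vs the numpy reference stepper for one
        noise-free excitatory cell under tonic drive."""
        from thetanest import neurons as nr

        cfg = NetworkConfig(counts={"CA1": (1, 1)}, seed=0, noise_on=False,
                            duration_ms=300.0, z_extent_um=20.0,
                            geometry_scale_xy=0.01, a_inter={}, a_intra={},
                            init_vm_range_mv=(-70.0, -70.0),
                            oscillator=OscillatorEnsembleParams(
                                theta_gain_na=0.0))
        model = build_network(cfg)
        n_steps = 3000
        tonic = 0.4
        tr = model.run(ext_currents={"CA1": (np.full(n_steps, tonic),
                                             np.zeros(n_steps))}, seed=0)
        cls = cfg.exc_params
        state = nr.init_state(cls, 1, vm_mv=-70.0)
        v_ref = np.empty(n_steps)
        for k in range(n_steps):
            state, _ = nr.step_neuron(state, cls, i_stim_na=tonic, dt_ms=0.1,
                                      t_ms=k * 0.1)
            v_ref[k] = state.vm_mv[0]
        # identical update rules, table interpolation the only difference;
        # sub-threshold trajectories agree tightly, spike-time jitter is
        # checked through the spike count
        first_spike = np.argmax(v_ref >= -20.0)
        assert np.max(np.abs(tr.vm_mon_mv[:first_spike - 5]
                             - v_ref[:first_spike - 5])) < 0.2
        ref_spikes = np.sum((v_ref[1:] >= -20) & (v_ref[:-1] < -20))
        t_e, _ = tr.spikes_for("CA1", "E")
        assert abs(t_e.size - ref_spikes) <= 1

    def test_spike_buffer_overflow_reported(self, small_ei_model):
        m = small_ei_model.with_updates(spike_rate_allowance_hz=0.05)
        with pytest.raises(SimulationError, match="buffer"):
            m.run(ext_currents={"CA1": (1.0, 1.0)}, duration_ms=1500.0,
                  seed=0)

    def test_unknown_stim_target_rejected(self, small_ei_model):
        with pytest.raises(ValueError):
            small_ei_model.run(protocol=StimulusProtocol(target_area="DG"),
                               duration_ms=100.0)

    def test_desk_scale_compensation_structure(self, tiny_loop_model):
        comp = tiny_loop_model.compensation
        # the long-range excitatory kernel loses much more in-degree to the
        # thin slice than the local inhibitory one
        assert comp["intra:EC:E->I"] > 2.0
        assert comp["intra:CA1:I->E"] < 0.5 * comp["intra:CA1:E->I"]
        for (src, dst) in (("EC", "DG"), ("CA1", "EC")):
            assert comp[f"inter:{src}->{dst}:E->E"] == \
                comp[f"inter:{src}->{dst}:E->I"]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(dt_ms=0.0)
        with pytest.raises(ValueError):
            NetworkConfig(duration_ms=100.0, burn_in_ms=200.0)


class TestEICircuit:
    def test_gamma_oscillation_under_strong_tonic_drive(self, small_ei_model):
        """PING: coupled E-I circuit under tonic drive oscillates in the
        gamma band; spectral peak between 30 and 120 Hz."""
        from thetanest.analysis import binned_rate, psd_and_bandpower

        n_steps = 20000
        tr = small_ei_model.run(
            ext_currents={"CA1": (np.full(n_steps, 0.7),
                                  np.full(n_steps, 0.7))},
            duration_ms=2000.0, seed=4)
        te, _ = tr.spikes_for("CA1", "E")
        rs = binned_rate(te, 200, 2000.0)
        x = rs.rate_hz[int(500 / 0.5):]
        f, p, _ = psd_and_bandpower(x - x.mean(), rs.fs)
        sel = (f >= 20) & (f <= 200)
        peak = f[sel][np.argmax(p[sel])]
        assert 30.0 <= peak <= 120.0

    def test_decoupling_removes_ei_interaction_structure(self,
                                                         small_ei_model):
        """PING rests on reciprocal E-I coupling: with it, the E and I
        population rates are strongly cross-correlated within one gamma
        cycle; decoupled populations are driven independently and lose
        that structure."""
        decoupled = build_ei_circuit(200, 20, seed=11, a_intra={
            "CA1": {"E->E": 0.0, "E->I": 0.0, "I->E": 0.0, "I->I": 0.0}})
        n_steps = 20000
        peak_corr = {}
        for tag, model in (("coupled", small_ei_model),
                           ("decoupled", decoupled)):
            tr = model.run(ext_currents={"CA1": (np.full(n_steps, 0.7),
                                                 np.full(n_steps, 0.7))},
                           duration_ms=2000.0, seed=4)
            rates = {}
            for cls, n in (("E", 200), ("I", 20)):
                t, _ = tr.spikes_for("CA1", cls)
                counts = np.histogram(t, np.arange(500.0, 2000.1, 1.0))[0]
                rates[cls] = counts - counts.mean()
            best = 0.0
            denom = (np.std(rates["E"]) * np.std(rates["I"])
                     * rates["E"].size) + 1e-30
            for lag in range(-15, 16):
                c = abs(np.dot(np.roll(rates["E"], lag), rates["I"])) / denom
                best = max(best, c)
            peak_corr[tag] = best
        assert peak_corr["coupled"] > 2.0 * peak_corr["decoupled"]
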