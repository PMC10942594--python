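"""Shared fixtures: small models and synthetic signals, all seeded."""

import numpy as np
import pytest

from thetanest.network import NetworkConfig, build_ei_circuit, build_network
from thetanest.kuramoto import OscillatorEnsembleParams


@pytest.fixture(scope="session")
def small_ei_model():
    """Compact 200E/20I pyramidal-interneuron circuit (CA1-like coupling)."""
    return build_ei_circuit(200, 20, seed=11)


@pytest.fixture(scope="session")
def tiny_loop_model():
    """Very small closed-loop model of all four areas, for structural and
    stimulation-contract tests (dynamics at this size are not calibrated)."""
    cfg = NetworkConfig(
        scale=0.02, seed=3, duration_ms=1500.0,
        oscillator=OscillatorEnsembleParams(theta_gain_na=0.3),
        a_inter={("EC", "DG"): 2.0, ("EC", "CA3"): 0.2, ("DG", "CA3"): 0.2,
                 ("EC", "CA1"): 2.0, ("CA3", "CA1"): 2.0, ("CA1", "EC"): 0.2},
    )
    return build_network(cfg)


@pytest.fixture(scope="session")
def pac_signal_pair():
    """(coupled, uncoupled) synthetic signals of matched length and noise."""
    from thetanest.fixtures import make_pac_signal

    _, coupled = make_pac_signal(duration_s=20.0, fs=1000.0, depth=1.0,
                                 noise_sd=0.1, seed=5)
    _, flat = make_pac_signal(duration_s=20.0, fs=1000.0, depth=0.0,
                              noise_sd=0.1, seed=5)
    return coupled, flat
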