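"""Frozen desk-scale reference parameterization.

The package's study configuration: a 1/20-scale septo-hippocampal loop
(1,610 neurons) whose theta input gain and inter-area connection strengths
were set by the six-step tuning procedure (noise off, fixed build seed).
These constants play the role of the published gain table for the
desk-scale model; re-running :func:`thetanest.tuning.tune_gains` on
``reference_config()`` reproduces them.

Operating points along the drive axis (matching the published theta-
amplitude axis of the regime map):

* ``WEAK_DRIVE_NA``       0.05 — oscillations abolished; trains can
  restore activity only while they last;
* ``SWITCHABLE_DRIVE_NA`` 0.11 — no spontaneous activity, but a single
  pulse switches the loop into persistent theta-nested gamma;
* ``TUNED_DRIVE_NA``      0.16 — output of tuning step 6;
* ``HEALTHY_DRIVE_NA``    0.20 — spontaneous theta-nested gamma (the
  healthy-state theta amplitude of the published regime map).
"""

from __future__ import annotations

from dataclasses import replace

from .kuramoto import OscillatorEnsembleParams
from .network import NetworkConfig

__all__ = [
    "DESK_SCALE",
    "DESK_BUILD_SEED",
    "TUNED_GAINS",
    "TUNED_DRIVE_NA",
    "HEALTHY_DRIVE_NA",
    "SWITCHABLE_DRIVE_NA",
    "WEAK_DRIVE_NA",
    "reference_config",
]

DESK_SCALE = 0.05
DESK_BUILD_SEED = 7

TUNED_GAINS = {
    ("EC", "DG"): 1.1,
    ("EC", "CA3"): 0.1,
    ("DG", "CA3"): 0.1,
    ("EC", "CA1"): 2.1,
    ("CA3", "CA1"): 2.1,
    ("CA1", "EC"): 0.3,
}

TUNED_DRIVE_NA = 0.16
HEALTHY_DRIVE_NA = 0.20
SWITCHABLE_DRIVE_NA = 0.11
WEAK_DRIVE_NA = 0.05


def reference_config(theta_gain_na: float = HEALTHY_DRIVE_NA,
                     **overrides) -> NetworkConfig:
    """Desk-scale closed-loop configuration at a chosen drive level."""
    osc = overrides.pop(
        "oscillator",
        OscillatorEnsembleParams(theta_gain_na=theta_gain_na))
    if osc.theta_gain_na != theta_gain_na:
        osc = replace(osc, theta_gain_na=theta_gain_na)
    base = dict(
        oscillator=osc,
        scale=DESK_SCALE,
        seed=DESK_BUILD_SEED,
        a_inter=dict(TUNED_GAINS),
        duration_ms=6000.0,
        noise_on=True,
    )
    base.update(overrides)
    return NetworkConfig(**base)
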