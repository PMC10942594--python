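# thetanest

A hybrid computational model of theta-nested gamma oscillations in the
septo-hippocampal system, built to study how electrical stimulation
interacts with ongoing hippocampal rhythms — for computational
neuroscientists and neurostimulation researchers who need a tractable
model in which both the theta rhythm's amplitude *and* its phase respond
dynamically to network activity.

## The model

Most hippocampal network models drive theta-nested gamma with a fixed
sinusoidal input, which cannot express **theta phase reset** — the
realignment of the ongoing rhythm by a salient input or stimulation pulse.
`thetanest` instead represents the medial septum as N coupled Kuramoto
phase oscillators,

    dθᵢ/dt = ωᵢ + (k/N) Σⱼ sin(θⱼ − θᵢ) + G_reset · X(t) · Z(θᵢ),
    Z(θ) = −sin(θ − θ_peak),

whose collective output — the order parameter r = (1/N) Σ e^{jθᵢ}, with
synchrony A = |r| and phase φ = arg r — is delivered as a rectified-cosine
current I_θ = G_θ (A cos φ + 1)/2 to the entorhinal cortex of a
conductance-based network: single-compartment Hodgkin–Huxley pyramidal
cells (Na, K, Ca, CAN, M currents, calcium dynamics) and fast-spiking
interneurons in EC, DG, CA3 and CA1, wired by distance-dependent
probabilistic rules on a slice geometry (tri-synaptic EC→DG→CA3→CA1 path,
monosynaptic EC→CA3/CA1, feedback CA1→EC). The CA1 firing rate X(t)
closes the loop through the oscillators' reset term, so strong hippocampal
activity — spontaneous or evoked by stimulation — pulls the theta phase
toward its peak along the biphasic phase-response function Z.

The package ships the full experiment and analysis stack around the model:
ramping and pulsed drive of reduced E-I circuits, single-pulse /
phase-targeted / pulse-train stimulation protocols, the six-step gain
tuning procedure, and spectral + phase-amplitude-coupling analyses (Welch
PSD, spectrograms, Tort modulation index with noise-injected
comodulograms, preferred phase, phase response curves). A Wilson–Cowan
mass model coupled to the same oscillator ensemble demonstrates that the
reset mechanism is independent of the conductance-based substrate.
`docs/methods.md` documents every modeling choice, the desk-scale harness
(1/20-size populations with in-degree-conserving compensation) and known
limitations.

## Worked example

`examples/theta_nested_gamma.py` runs the desk-scale reference model
(tuned gains, healthy 0.2 nA septal drive) for six seconds and prints:

```
septal drive G_theta = 0.2 nA
area   E rate (Hz)   I rate (Hz)   [2-6 s window]
EC          13.8          62.8
DG          11.2          38.6
CA3         10.5          20.0
CA1         13.3          30.1

CA1 theta peak: 5.0 Hz (the reset feedback slows the 6 Hz pacemaker)
CA1 gamma ridge at theta peaks: 60 Hz
theta-gamma modulation index: 0.144 (0 = no coupling, 1 = all gamma in one phase bin)
```

The network oscillates spontaneously: gamma bursts (~60 Hz) ride the peaks
of a theta rhythm that runs at 4–5 Hz rather than the pacemakers' 6 Hz,
because each CA1 burst feeds back and stalls the ensemble phase near the
theta peak — the same reset pathway that makes single-pulse stimulation
able to realign the rhythm. The other scripts in `examples/` each exercise
one capability: gamma generation under ramping drive, the ensemble phase
response curve, single-pulse switching of the quiescent loop (and how
phase reset removes its dependence on stimulation phase), PAC metrics on
synthetic signals, mass-model reset, and the tuning procedure.

A thin command-line interface wraps the same library calls:

```bash
thetanest simulate --config run.yaml --out trace.h5
thetanest analyze --trace trace.h5 --metrics psd,mi --out report/
thetanest tune --config run.yaml --out gains.yaml
```

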