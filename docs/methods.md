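# Model and methods

`thetanest` implements a hybrid model of theta-nested gamma oscillations in
the septo-hippocampal system: an abstract medial-septum theta generator
(coupled phase oscillators with phase reset) drives a conductance-based
excitatory/inhibitory network of the hippocampal formation (EC, DG, CA3,
CA1), whose CA1 output feeds back onto the oscillators. The package also
implements the stimulation protocols (single pulses, phase-targeted pulses,
pulse trains) and the oscillation-analysis stack used to characterize the
resulting dynamics.

## Septal theta generator

Each of N = 250 oscillators carries a phase θᵢ evolving as

    dθᵢ/dt = ωᵢ + (k/N) Σⱼ sin(θⱼ − θᵢ) + G_reset · X(t) · Z(θᵢ)

with natural frequencies ωᵢ ~ N(2π·6 Hz, 2π·0.5 Hz), synchronization ratio
k/N = 15 (the mean-field identity (k/N)Σⱼ sin(θⱼ−θᵢ) = (k/N)·N·A·sin(φ−θᵢ)
makes the step O(N); note the total coupling scales with N), reset gain
G_reset = 4, and the biphasic phase-response function
Z(θ) = −sin(θ − (θ_peak + φ_offset)), θ_peak = 0. X(t) is the instantaneous
CA1 excitatory firing rate (exponential kernel, τ_FR = 10 ms; each spike
adds 1/(N_CA1·τ_FR), so X is a per-neuron rate in 1/s). The collective
output is the order parameter r = (1/N)Σe^{jθᵢ}, with synchrony A = |r| and
ensemble phase φ = arg r (the modulus/argument reading; Re/Im would not
yield a phase), and the theta drive delivered to all EC neurons is the
rectified cosine I_θ = G_θ(A·cos φ + 1)/2 ∈ [0, G_θ].

Phases are initialized uniformly on the circle (with k/N = 15 the ensemble
synchronizes to A > 0.9 within a few hundred milliseconds, so no special
burn-in is needed); φ_offset defaults to 0, the physiological setting.

## Neurons

Single-compartment Hodgkin–Huxley neurons. Pyramidal/granule cells
(A = 29·10³ µm²): leak, transient Na (m³h), delayed-rectifier K (n⁴),
high-threshold Ca (m²h), CAN (m²) and M-type K (p) currents, plus
intracellular calcium. Fast-spiking basket cells (A = 14·10³ µm²): leak,
Na, K with Wang–Buzsáki kinetics. Rate constants are in ms⁻¹ with
τ = 0.2/(α+β) for the rate-based gates (the 0.2 is the 5× kinetic scale of
the source kinetics); the M gate uses the bell-shaped Yamada time constant
τ_p = 1000/(3.3·e^{(V+35)/20} + e^{−(V+35)/20}) ms (≈ 233 ms at −35 mV),
which is what makes it an adaptation current.

Calcium obeys d[Ca]/dt = −I_Ca/(2F·d·A) + ([Ca]∞ − [Ca])/τ_Ca with shell
depth d = 1 µm, τ_Ca = 1 s and [Ca]∞ = 0.24 µM; an inward calcium current
raises [Ca]. CAN gating rates are α = 0.0002·e^{1.4·[Ca]/[Ca]_crit},
β = 0.0002·e^{1.4} ms⁻¹. **[Ca]_crit = 0.2 µM is a calibrated constant**:
it was set so that a single suprathreshold volley recruits enough CAN
conductance to support rebound bursting and stimulation-switchable
persistent states while the resting state ([Ca] = 0.24 µM, m∞ ≈ 0.3,
τ ≈ 170 ms) stays stable. At weaker sensitivities the model loses all
stimulation-induced persistence; see Limitations.

Membrane noise: the printed noise amplitudes (1000 µV excitatory, 100 µV
inhibitory) are implemented as the *stationary* voltage fluctuation under
the leak time constant — per-step increments of σ·√(2·dt/τ_m) — so isolated
cells remain silent without drive at any dt (a literal per-step reading
would integrate to an ~11 mV fluctuation and make pyramidal cells fire
spontaneously, contradicting the model's zero-drive silence).

Spike detection: upward crossing of −20 mV with a 2 ms hold-off.

## Synapses and connectivity

Biexponential conductance synapses, I = g(V−E_rev), dg/dt = (h−g)/τ_g,
dh/dt = −h/τ_h, with AMPA-like (E = 0 mV, rise 0.3 ms, decay 3 ms) and
GABA-A-like (E = −80 mV, rise 1 ms, decay 10 ms) kinetics. The reversal
potentials and time constants are inherited constants (not printed in the
source tables); the 3 ms AMPA decay was chosen because a 5 ms decay tips
the closed loop from a drive-graded oscillatory continuum into a runaway
regime with depolarization-blocked interneurons once the CA1→EC feedback
closes. A presynaptic spike increments h by a connection-specific amount
(e.g. CA1 I→E 1800 pS, EC E→I 20 pS, DG→CA3 180 pS). The (g, h) cascade is
propagated with its exact linear one-step propagator, so conductance traces
match the closed-form biexponential to machine precision at any dt.

Neurons occupy a 15-mm-thick slice whose coronal cross-section consists of
per-area principal-cell and oriens bands (annular sectors); placement is
blue-noise (Poisson-disk) sampling refined by Lloyd relaxation, z uniform
on [0, 15] mm. Within an area, ordered pairs connect with probability
A_intra·exp(−D²/2σ²) (3D distance; σ = 2500 µm excitatory / 350 µm
inhibitory, maxima per the published table). Between areas only excitatory
projections exist, with probability min(1, A_inter·exp(−Δz²/2σ²)),
σ = 1000 µm; where the kernel exceeds 1 the excess multiplies the synaptic
weight (multiple contacts), which keeps the expected input exactly linear
in the gain A_inter at every scale — at full scale this reduces to the
plain rule for all but the nearest-z pairs of the strongest projection.
The band dimensions are deliberately compact relative to the anatomical
formation: with the printed 15-mm z-dilution of the σ = 350 µm inhibitory
kernel, wider bands leave pyramidal cells with too little inhibition to
sustain pyramidal–interneuron gamma. All wiring rules depend only on
distances, so this is a parameter choice, not a change of model class.

## Desk scale

The full model (32,200 neurons) exceeds interactive budgets, so the
package's study configuration runs at scale 1/20 (1,610 neurons): counts
×0.05 and slice thickness ×0.05, which preserves volumetric density and
therefore the local (inhibitory) in-degrees exactly. Long-range kernels
lose in-degree to boundary truncation; each projection class's increment is
multiplied by the ratio of expected full-size to desk-scale in-degree
(Monte-Carlo over the kernel, gain-independent for the inter-area classes
by the linearity above). This conserves the mean synaptic input per target
class by class. The reduced two-population circuit used for the ramp and
pulsed-drive experiments is built compact (point-like geometry), i.e. the
D→0 limit where connection probabilities equal the within-area maxima.

## Simulation

Single global clock at dt = 0.1 ms: oscillators (explicit Euler on phases),
neurons (exponential Euler on gates via lookup tables built from the exact
rate expressions; explicit Euler on V and calcium), synapses (exact
propagator) and the X(t) feedback advance in lockstep, with X consumed by
the oscillators at the next step. The core is a jit-compiled loop;
membrane noise is pre-generated in chunks outside the kernel. Runs are
bitwise-reproducible given the build seed and run seed. Stimulation is an
intracellular current applied equally to all neurons of the target area;
phase-targeted protocols are realized with a matched no-stimulation pass
that supplies the theta phase series (identical seeds up to pulse onset).

## Tuning

The six-step procedure targets a 6 Hz excitatory rate and 6 Hz drive
oscillation via the distance J = √((f_exc−6)² + (f_osc−6)²), minimized on
one-dimensional grids (G_θ: 0–0.5 nA step 0.01; EC→DG: 0–20 step 0.1;
joint (EC,DG)→CA3 and (EC,CA3)→CA1: 0–5 step 0.1), noise off, 3 s runs
scored on the last second, ties toward the smaller value. Step 5 decouples
CA1, drives it with a 6 Hz sinusoid (amplitude itself tuned first) and
tunes CA1→EC with the external EC drive removed; step 6 halves that gain,
restores the loop and retunes G_θ. Two desk-scale adaptations: grids are
scanned coarse-to-fine (every 5th point, then the native step around the
coarse argmin, with an early stop once J has clearly left the basin), and
the step-6 halving is *iterated* — after each halving and G_θ retune, a
noise-on verification run must show mean excitatory rates below 10× target,
else the feedback is halved again (the same remedy the procedure already
applies once, applied until the "complex dynamics" it targets are actually
tamed). The frozen result at scale 0.05 (build seed 7): EC→DG 1.1,
(EC,DG)→CA3 0.1, (EC,CA3)→CA1 2.1, CA1→EC 0.3, G_θ 0.16 nA
(`thetanest.reference`).

## Operating points

Sweeping G_θ reproduces the drive-graded regime structure: below ~0.1 nA
any evoked activity is transient; around 0.11 nA the loop is quiescent but
a single 7 nA pulse switches it into persistent theta-nested gamma; above
~0.22 nA oscillations arise spontaneously. The healthy reference drive is
0.2 nA — the published healthy-state theta amplitude. At that point the
CA1 rate spectrum peaks near 4–5 Hz (the reset feedback slows the 6 Hz
pacemaker by stalling the ensemble phase near the theta peak) with a gamma
ridge near 60 Hz during theta-peak epochs. With reset enabled, pulses at
theta peak and trough are equally able to switch the quiescent loop on;
with reset disabled, trough pulses are markedly less effective.

## Analysis stack

Instantaneous rates: 5 ms rectangular windows, 90% overlap (0.5 ms step).
PSD: Welch, 1 s windows, 90% overlap (1 Hz resolution); band power by
Simpson's rule. Spectrograms: Hann STFT, 100 ms windows, 99% overlap
(10 Hz resolution). Modulation index: band-pass (zero-phase FIR, 20%
transition widths) the phase (3–9 Hz) and amplitude (40–80 Hz) bands,
Hilbert phase/amplitude, mean amplitude in 72 5° phase bins, KL divergence
to uniform normalized by log 72 (MI ∈ [0, 1]). Comodulograms: MI over
1 Hz phase bands (80% overlap) × 10 Hz amplitude bands (90% overlap), with
uniform noise of 20% of the signal maximum injected first — filtering a
spectrally empty simulated rate yields a flat signal and a spurious MI,
which the noise suppresses; the injection seed is recorded. PAC analyses
internally resample signals to 4× the highest analysis band (linear, so MI
properties are unaffected). PRC: one theta cycle split into π/8 bins; for
each phase and amplitude, paired stimulated/unstimulated runs with
identical seeds, Δφ = wrapped difference of theta phase 2.5 ms after pulse
onset, advance positive.

## What the synthetic signals do and do not show

The PAC fixture (carrier amplitude ∝ (1+cos θ)/2 plus noise) has a single,
stationary coupling at known bands — it validates the metric chain, not
the model. Conversely, simulated rates lack broadband background power,
which is exactly why the comodulogram needs the noise-injection fix.
Passing analysis tests therefore certify the measurement pipeline;
conclusions about the network come from the simulation tests.

## Known limitations

* The desk-scale loop's tuned operating point carries excitatory rates
  above the 6 Hz target once noise ignites the oscillation (≈ 12–30 Hz),
  and the inhibitory population mean reaches ≈ 35–60 Hz depending on the
  drive; the 10:1 E:I rate relation holds best in EC, least in the
  sparsely-interneuron DG.
* The CAN-supported persistent state does not self-terminate: after a
  suprathreshold kick at zero or weak drive, bursting continues instead of
  fading within ~250 ms. With one spike per cell per burst, the calcium
  gained per cycle equals what decays per cycle at equilibrium, so
  regeneration is structurally marginal and no calcium-scale setting gives
  a damped exactly-two-burst response; the rebound latency and CAN
  dependence are reproduced, the decay is not.
* The reduced circuit's interneuron-entrainment resonance sits at its own
  gamma frequency (~50–60 Hz) rather than in fast gamma.
* One theta generator, basket cells as the only interneuron class, no
  synaptic delays, no plasticity, intracellular (not extracellular)
  stimulation — inherited simplifications of the modeled system.
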