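# Methods

`thetafear` simulates how the frequency of the hippocampal theta rhythm
during contextual fear conditioning controls the strength of the learned
context–threat association, and thereby conditioned freezing. It is a
forward biophysical simulation: nothing is fitted to data, and every
reported quantity is regenerated from the model, the parameter set and a
seed.

## Model

**Network.** A population of N amygdalar "fear cells" each receives
feed-forward excitation from its own subpopulations of M hippocampal place
cells per environmental compartment (a safe and a threatening compartment;
2M spines per cell in total). Place-cell spike trains are theta-modulated
inhomogeneous Poisson processes with rate proportional to
`1 + sin(2π f_θ t)`, normalised so each cell fires one spike per theta
cycle in expectation. Fear cells fire exogenous homogeneous Poisson trains
at `r_safe = 0.85 Hz` or `r_threat = 1.85 Hz` while the simulated animal
occupies the corresponding compartment, standing in for noxious (US)
drive.

**Spine voltage.** Each synapse is a dendritic spine whose potential is a
linear superposition around rest (−65 mV) of: weighted EPSPs (double
exponential, τ₁ = 50 ms and τ₂ = 5 ms, gain calibrated so the unitary
kernel peaks at 8 mV, suppressed by a factor (1 − ACh)); back-propagating
action potentials triggered by the cell's own output spikes (fast + slow
double exponential, 3 ms / 25 ms, peaking at 100 mV); and a subthreshold
theta oscillation of amplitude 3 mV in phase with the place-cell rate
(switchable; the parameter is listed in the source model but enters no
printed voltage equation, so the membrane — its only voltage equation —
is where we add it).

**Calcium and plasticity.** NMDA receptor current is the product of a
presynaptic gating trace (0.5·e^(−t/50 ms) + 0.5·e^(−t/200 ms), summed
linearly over spikes), the channel opening probability P₀ = 0.5, the
conductance G = −1/500 µM/(ms·mV) and the magnesium-block term
H(V) = (V − 130)/(1 + e^(−0.062 V)[Mg]/3.57). Calcium integrates this
influx with τ_Ca = 50 ms. The synaptic strength follows the
calcium-control rule

    dW/dt = η([Ca]) · (Ω([Ca]) · ACh − λ·W)

with Ω the 0.25-baseline double-sigmoid (thresholds 0.35 / 0.55 µM,
slopes 80) and η the calcium-dependent learning rate in s⁻¹
(η(0) ≈ 10⁻⁴ s⁻¹ with P₂ = 10⁻⁵). Two readings of the decay term exist;
we default to the weight-proportional form λ·W of the source plasticity
model because the constant-decay alternative, combined with λ = 1 in the
rate-induced protocol, makes any increase of synaptic strength above
baseline mathematically impossible (Ω ≤ 1), contradicting the
frequency-dependent potentiation the protocol is designed to show. The
constant-decay reading remains available (`lam_scales_w: false`), as does
the alternative η-denominator constant (`p2`).

## Protocols

**Rate-induced plasticity ("tetanus").** 100 presynaptic spikes at a
chosen frequency, no output spiking, λ = 1, EPSP gain s = 1.45. The
default drive is the same theta-modulated Poisson train the place-cell
generator produces, together with the subthreshold theta oscillation —
the protocol probes the frequency content of the rhythmic drive the
conditioning phase actually delivers (a deterministic evenly spaced train
without the theta term is available via `train="regular"`; it yields the
classic low-frequency-depression / high-frequency-potentiation curve with
its rise at higher frequencies). ACh gates are protocol switches here:
the plasticity gate is open (the Ω coefficient is 1) while EPSPs are
active — the stated s = 1.45 would otherwise be dead code.

**Conditioning.** 100 theta periods in each compartment at ACh = 1
(EPSPs suppressed, plasticity on), theta at 6.0 Hz (baseline) or 5.5 Hz
(anxiolytic-like reduction). Because EPSPs are suppressed, spine voltage
and calcium are independent of the evolving weights, and each epoch
integrates in closed vectorised form; a fused numba kernel computes the
identical recursions in one pass (cross-checked against the numpy path in
the tests). Synapses of the unoccupied compartment receive no input and
follow the closed-form zero-calcium drift (negligible: η(0) ≈ 10⁻⁴ s⁻¹).

**Recall.** ACh = 0 (EPSPs on, plasticity frozen), theta at 5 Hz, 25
periods per compartment. Each fear cell's somatic potential is the
average over all its 2M spines — the silent spines of the other
compartment dilute the drive — with EPSP amplitude scaled by W/w0 so the
calibrated 8 mV peak is the pre-conditioning baseline. The soma fires
when crossing −55 mV; all spines then reset to −75 mV and relax back to
rest with the membrane time constant (20 ms), with a 2 ms absolute
refractory period. BPAPs are excluded from the somatic drive during
recall (plasticity is off; feeding 100 mV BPAPs back into the average
would only self-excite). Freezing is declared in a compartment when the
population mean output rate exceeds r_freeze = 1.5 Hz; the freezing
probability is the fraction of seeded simulations that freeze.

**Spectra.** Per-cell spike-train autocorrelations (10 ms bins, lags to
1 s, zero-lag self-pairs excluded) are mean-normalised, completed
symmetrically, Fourier transformed, restricted to ≤ 50 Hz and smoothed
with a σ = 2 Hz Gaussian; per-cell spectra are averaged, never pooled.

## Calibration of unstated parameters

The source parameter table omits the extracellular magnesium
concentration and both population sizes, and prints an input-spike count
K = 900 that conflicts with the stated one-spike-per-cycle normalisation
over 100-cycle epochs. We reconcile K = 900 as 100 cycles × M = 9 place
cells per fear cell and give each fear cell an independent place-cell
subpopulation; with a single shared population, shared input noise places
a floor on the across-simulation variance of the population mean rate
that makes the published freezing contrast unattainable at any population
size. The remaining free parameters were set by one grid search
minimising the distance of the two threat-compartment freezing
probabilities from their published values (92% and 18%), refined with
300-simulation estimates on the magnesium axis (the freezing fractions
are steep in [Mg]), yielding [Mg] = 1.965 mM, N = 32 fear cells, M = 9,
w₀ = 0.5, frozen thereafter as the package defaults (estimated fractions
0.95 and 0.21 at that point). At the conventional [Mg] = 1.0 mM the model is in
runaway potentiation from place-cell input alone (every compartment
saturates recall and freezes always); the calibrated magnesium
concentration moves rest-voltage calcium below the depression threshold
so that potentiation is dominated by BPAP-coincident input, which is what
makes the compartments distinguishable at all.

## Numerical choices

Forward Euler at dt = 0.1 ms for the two ODEs (calcium, weight); the
exponential kernels are evaluated by exact first-order recursions
(`lfilter`), so kernel values at grid points carry no integration error.
Halving dt changes rate-protocol final weights by < 2% (tested). The
weight ODE under λ·W is linear with time-varying coefficients and is
integrated in closed form along whole epochs; under the constant-decay
reading the per-step floor at 0 is computed with the Lindley reflection
identity. Both are verified against literal per-step loops. The numba
kernel evaluates η and Ω from dense lookup tables (grid 5×10⁻⁴ µM,
linear interpolation; relative error ~10⁻⁵ on the weights). Spike times
live on the integration grid (per-step Bernoulli thinning, warning if
rate·dt ≥ 0.1). Seeds derive from a single master `SeedSequence` spawned
per simulation → per phase → per cell → per stream, so results are
bit-reproducible and independent of execution order.

## What the generator does and does not emulate

Place cells are compartment-selective theta-modulated Poisson units with
a common LFP phase and no spatial geometry: compartment occupancy is a
fixed epoch, there is no trajectory, remapping, phase precession, or rate
variability across cells. Fear-cell US drive is exogenous Poisson spiking
rather than a nociceptive pathway. Passing tests therefore show that the
calcium-control mechanism converts a 0.5 Hz theta-frequency difference
into a behaviourally thresholded difference in conditioned output — not
that these simplifications hold in real recordings.

## Known limitations

* Two acceptance-level properties of the published account are not
  reproduced at the calibrated operating point and their checks are left
  failing deliberately. (1) The change in rate-protocol weights between
  4 and 9 Hz does not exceed the change between 9 and 14 Hz: the
  potentiation branch keeps rising through ~14 Hz; compressing the whole
  sigmoid into 4–9 Hz requires ~1.5× more calcium gain, which places the
  conditioning protocol in runaway potentiation and destroys the freezing
  result. (2) The theta-band spectral peak after 6 Hz conditioning
  exceeds the 5.5 Hz peak by a factor ~1.5–2, not ≥ 5: the graded recall
  rate contrast (~1.33×) that produces the 92%/18% threshold crossings
  bounds the achievable power contrast; an order-of-magnitude power ratio
  would need near-silent recall after 5.5 Hz conditioning, inconsistent
  with an 18% freezing fraction in this architecture.
* The freezing probabilities depend on the calibrated population sizes
  and magnesium concentration; this dependency is declared, not hidden.
* The model has no inhibition, no amygdalar recurrence, and no
  extinction/reconsolidation dynamics; anxiolytic action is represented
  solely as the theta-frequency argument.
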