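# Methods

## The model

A layer II medial-entorhinal stellate cell is represented as a single
cylindrical compartment, 70 µm in diameter and 75 µm long; only the lateral
surface contributes membrane area (the convention of compartmental
simulators), giving 1.649×10⁻⁴ cm². Units throughout are mV, ms, mM,
mS/cm², µA/cm² and µF/cm², so that `g·(V−E)` is a current density and
`dV/dt = I/C_m` is in mV/ms without conversion factors.

The passive membrane is an RC shell: specific resistance R_m (base
40 kΩ·cm²), specific capacitance C_m (base 1 µF/cm²), and a leak reversal
fixed at −77 mV so that the cell with every active conductance removed
rests exactly there. Nine active conductances are layered on top:

| channel | gating | current law | reversal |
|---|---|---|---|
| NaF | m³h | Ohmic | +50 mV |
| KDR | n⁴ | Ohmic | −90 mV |
| HCN | fast + slow components, conductance ratio 1.85 | Ohmic | −20 mV |
| NaP | m·h | Ohmic | +50 mV |
| KA | m·h | Ohmic | −90 mV |
| HVA Ca²⁺ | m³h | GHK | — |
| LVA Ca²⁺ | m²h·s([Ca]) | GHK | — |
| KM | m | Ohmic | −90 mV |
| SK | 6-state Markov, Ca²⁺-gated | Ohmic | −90 mV |

Every Hodgkin–Huxley gate follows first-order kinetics
`dm/dt = (m∞(V) − m)/τ_m(V)`. Steady states are Boltzmann sigmoids in the
tabulated half-voltage and slope (the HCN components raise the whole
sigmoid bracket to fractional powers, −1.36 fast and −58.5 slow, which
places their effective half-activations near −78 and −73 mV); time
constants are either rational functions of voltage built from terms of the
form `x/(1−e^(−x))` — evaluated by the analytic limit at their removable
singularities — or constants (HVA: 0.92 ms activation, 250 ms
inactivation). Each gate's τ carries a dimensionless scale factor that the
population search samples in 0.8–1.2.

Calcium channels use the Goldman–Hodgkin–Katz driving term
`−s·(1−(ci/co)·e^(V/s))·efun(V/s)` with `s = RT/2F` expressed through the
25-mV-at-20 °C thermal-voltage convention (13.097 mV at the simulated
34 °C) and `efun(x) = x/(eˣ−1)`; the tabulated "conductance" is the
permeability scale multiplying this term. The zero-current potential equals
the calcium Nernst potential by construction (covered by a test). Calcium
entering through HVA and LVA feeds a thin-shell cytosolic pool
(depth 0.1 µm) with first-order decay (τ_Ca, base 78 ms) toward a 100-nM
resting level; the influx term is `−10⁴·I_Ca/(36·depth·F)` with I_Ca in
mA/cm², implemented exactly as stated even though the 36 in the denominator
differs from the conventional 2F·depth form.

### The SK scheme and its consequences

The SK channel is a six-state Markov scheme: four closed states linked by
three sequential calcium-binding steps (forward rate α·[Ca] with
α = 10 µM⁻¹s⁻¹, backward β = 0.5 s⁻¹) and two open states reached from the
last two closed states (opening γ = 600 s⁻¹, closing δ = 400 s⁻¹ in the
default wiring; `ModelConfig(sk_opening="delta")` swaps the pair). The
stationary distribution is computed from the null space of the generator
and verified against a matrix-exponential relaxation of the master
equation.

These rate constants imply a per-site dissociation constant β/α = 50 nM,
well below the 100-nM resting calcium, so the scheme is ~55% open at rest
and saturates near 60%: SK behaves largely as a standing potassium
conductance rather than a spike-activated one. Two consequences are worth
knowing. First, the hand-tuned base parameter set lands three of the ten
validity measurements marginally outside their windows (rest −66.2 mV vs.
a −65 bound, input resistance 33.9 MΩ vs. 35, and 21 spikes at 400 pA vs.
16) while the other seven — including the perithreshold theta oscillations
— fall inside; the alternative δ-opening wiring repairs the subthreshold
trio but makes the cell fire at 100 pA, so no printed-rate-preserving
wiring satisfies all ten at once. Second, knocking out the calcium channels
(HVA/LVA) disinhibits firing on the base model but has near-zero median
effect across valid models, because the saturated calcium curve mutes the
Ca→SK→excitability pathway. Both observations are asserted at their actual
strength in the test suite rather than idealized.

## Numerics

The integrator advances gates by exponential Euler (exact for the linear
per-step gate equation), and voltage, calcium and the SK occupancies by
forward Euler (flux-form for SK, conserving total occupancy to round-off),
at a fixed 25-µs step. Voltage-dependent quantities — gate steady states,
the per-step relaxation factors `1−e^(−dt/τ)`, and the two GHK coefficients
(the driving term is linear in [Ca]) — are pre-tabulated per model on a
−120…+60 mV grid at 0.01 mV and linearly interpolated, the classic
rate-table device; a direct-evaluation reference integrator is kept in the
package and the two routes agree to <0.005 mV on cross-validation traces.
Integration aborts with a diagnostic when |V| exceeds 200 mV or calcium
becomes non-positive.

Two rate functions need guards: the NaP inactivation rate has a genuine
pole at +49.1 mV where the summed rate can go negative, so it is floored at
a small positive value (freezing a gate whose kinetics are ~seconds during
a ~1-ms spike peak); and the literal transcription of the KA β_h term is
non-physiological, so the symmetric form is the default with the literal
one behind `ModelConfig(ka_betah_as_printed=True)`.

Halving the step to 12.5 µs leaves all smooth measurements unchanged to
<1%; discrete quantities shift at their natural granularity (the 400-pA
spike count by ±2 of ~20, the oscillation frequency by one 0.33-Hz spectral
bin), as expected for threshold crossings of mixed-mode trains.

## Protocols and measurements

All protocols start from the state reached after 5 s of zero current; the
resting potential and its SD are the mean and SD of V over the following
second. The initial condition equilibrates every gate at the passive
−77-mV rest, which produces a brief onset transient (it can fire a spike or
two in the first ~100 ms even in quiescent models); measurements never
include it, and the spontaneous-firing screen for knockouts therefore
evaluates seconds 1–6 of the settle.

* **Sag**: −200 pA for 1 s; steady-state over peak deflection, both
  relative to the pre-step baseline, steady state read as the mean of the
  final 10 ms.
* **Input resistance**: eleven 1-s steps, −100…+100 pA in 20-pA increments;
  slope of the V–I line read at 1 s. Sweeps containing spikes flag the
  estimate.
* **Excitability**: 500-ms steps at 100 and 400 pA; spikes are upward
  crossings of −20 mV with a 1-ms lockout (−20 mV cleanly separates the
  <25-mV oscillation cluster from >60-mV action potentials); spike
  amplitude is the first 400-pA spike's peak minus the resting potential.
* **Impedance**: 15-s chirp, 0→15 Hz linear, 40 pA peak-to-peak; Z(f) is
  the ratio of Fourier transforms of response and stimulus on 0.5–15 Hz.
  f_R is the magnitude argmax, Q_R the ratio to the bin nearest 0.5 Hz, and
  Φ_L the integral of the positive (inductive) phase region.
* **Oscillation scan**: 21 five-second steps, 100–300 pA in 10-pA
  increments; the final 3 s of each sweep yield the mean potential, the
  peak-to-peak amplitude, and the frequency of the rectangular-window
  spectral peak (DC excluded). Sweeps below 0.5 mV peak-to-peak count as
  non-oscillating. The perithreshold frequency f_osc is the oscillation
  frequency of the largest zero-spike sweep, provided that sweep
  oscillates; otherwise f_osc is absent, which invalidates the model.

A model is **valid** when all ten measurements fall (inclusively) inside
their tabulated physiological windows.

## Stochastic search

Each candidate draws its 55 parameters independently and uniformly within
the tabulated ranges. Model k uses the RNG substream `(seed, k)`, so
populations are reproducible independent of batch size, worker count or
interruption (resuming a partial search reproduces the uninterrupted
result exactly). The battery short-circuits cheapest-first (rest → steps →
sag → V–I → chirp → oscillation scan) and stops at the first failed
criterion — an order that cannot change any validity decision but avoids
the 105-s oscillation scan for ~99% of candidates. Simulation failures are
recorded as invalid with their reason; they never abort a batch. The suite
exercises the search at 5,000 models (and extends the same stream to
10,000 for the knockout screen), sizes at which the observed valid
fraction can be compared with the ~0.3% expected from full-scale runs.

## Analytics

Pairwise parameter correlations are Pearson coefficients across valid
models (1,485 unique pairs for 55 parameters; constant columns are
reported missing, not zero). Distances between models use (a) Euclidean
distance on parameters min–max-rescaled to [0,1], bounded by √55, and
(b) Mahalanobis distance under the population covariance, normalized by the
distance between the all-minimum and all-maximum corner vectors; when a
population has no more models than parameters the covariance receives
diagonal loading ε = 10⁻⁶·tr(Σ)/55, recorded in the metric tag. Cross-set
comparisons use Kruskal–Wallis over sets plus two-sided pairwise
Mann–Whitney tests, reporting raw p-values without multiplicity
correction. The 14-measurement correlation panel combines the eight
intrinsic measurements with the six STA-derived ones (91 unique pairs).

## Virtual knockouts

A knockout zeroes exactly one maximal conductance (HCN's slow conductance
carries the fast component through the fixed ratio). Knockouts that fire
spontaneously at rest or enter depolarization block (a contiguous >100-ms
stretch above −20 mV during a step — a spike spends only ~1–2 ms there)
are excluded, since their measurement set cannot be completed. Changes are
percentages of the pre-knockout value; N₁₀₀ is an absolute count change
(its baseline is zero in every valid model), and the resting-potential
shift is additionally reported in mV because a percentage of a negative
baseline inverts sign. The no-change test is a two-sided one-sample
Wilcoxon signed-rank against zero (a rank-sum against an equal-size zero
vector is available behind a flag).

## Spike-triggered average

The noise standard deviation is calibrated by geometric bisection (firing
rate is monotone in drive) on 50-s probes until the rate is within
±0.25 Hz of 1 Hz; the ~1-Hz target keeps spikes isolated and aperiodic so
pre-spike segments are effectively independent. The STA is the mean
injected current over the 300 ms preceding each spike (spikes without full
history excluded), median-filtered over 1 ms for metric extraction. The
spectrum of the kernel zero-padded to 4 s (raw resolution 3.33 Hz is too
coarse to resolve either the 0.5-Hz reference or theta peaks; padding
interpolates the continuous spectrum) yields f_STA and Q_STA on
0.5–50 Hz. T_TCDW is the lag of the first zero crossing walking back from
the spike; T_ECDW is the STA-weighted RMS width of the spike-proximal
positive lobe, √(∫t²·STA²dt / ∫STA²dt) — a literal variant of the width
integrand that is dimensionally inconsistent is computed alongside for
auditability. The suite runs the base model at 200 s (≥150 spikes); the
acceptance script uses 300 s. Doubling the duration moves f_STA by less
than a spectral bin.

## The synthetic-trace generator

Measurement code is tested against constructed traces whose ground truth
is exact by construction: flat resting traces, sinusoidal oscillations of
known frequency/amplitude, sag-shaped step responses with prescribed peak
and steady-state deflections, triangular-waveform spike trains at
prescribed times, and frequency-domain RC chirp responses. These fixtures
validate the measurement operators — windowing, deflection bookkeeping,
spectral estimation, spike detection — independently of the ODE solver.
They deliberately contain none of the features that make real (or
simulated) traces hard: no channel noise, no spike-shape variability, no
drift, no mixed-mode transitions. Passing them shows the measurement
pipeline is correct, not that the biophysics is; the biophysics is checked
separately against passive closed forms, the dual-route integrator
comparison, and the population-level directionality of knockout effects.

## Known limitations

* The printed SK rate constants pin the scheme near saturation at resting
  calcium (see above); the three marginal base-model measurements and the
  muted population-level calcium-channel knockout effect both trace to
  this, and the alternative rate wiring is provided for sensitivity
  analysis rather than as a fix.
* Several time-constant expressions were reconstructed from typographically
  damaged sources; the readings adopted are the ones that yield
  physiological kinetics (documented per channel in `channels.py`), with
  the rejected literal variants kept behind configuration flags where they
  are well-defined.
* The model is deterministic and single-compartment: no stochastic channel
  gating, no morphology, no synaptic background — population conclusions
  apply to the ensemble dynamics of channels, not to channel-noise-driven
  phenomena.
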