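# Methods

## Measurement model

A scotopic flash ERG sweep is a stimulus-locked voltage trace sampled
uniformly (default 0.5 ms, i.e. 2 kHz) from 20 ms before to 200 ms after
flash onset. The extraction chain per (animal, eye, flash luminance) is:

1. **Averaging.** Repeated trials are averaged pointwise (10 repeats for
   the dimmer half of the flash range, 5 for the brighter half).
2. **Baseline.** Mean voltage over the pretrial window; by default the
   entire pretrial record (a configurable sub-window is supported, since
   acquisition systems differ in how much pretrial they store).
3. **a-wave.** Baseline-to-trough amplitude and trough latency, measured
   on the *unfiltered* average inside a search window (default 3–50 ms).
   Ties in the minimum resolve to the earliest sample. If the amplitude is
   below a detectability floor (default 10 µV — dim flashes), the trough
   reference for the b-wave falls back to (stimulus onset, baseline) and
   the row is flagged.
4. **OP isolation.** Digital Butterworth high-pass, 25 Hz cutoff, order 4,
   applied forward and backward (`sosfiltfilt`, odd-reflection padding of
   at least three filter time constants). Zero-phase filtering is
   essential here: OP implicit times are the headline metric and a causal
   pass would delay them by several ms. The effective magnitude response
   is the squared analytic Butterworth response, which the tests verify to
   <1% at 5–200 Hz.
5. **b-wave.** Trough-to-peak amplitude on the OP-subtracted trace, from
   the a-trough time to 150 ms. Conservation is exact by construction:
   OP trace + smooth trace = average.
6. **OP peaks.** The first four positive local maxima of the filtered
   trace within [a-implicit, b-implicit + 20 ms], clipped away from the
   first/last 10 ms of the record (filter edge transients). Peaks need a
   prominence of 5 µV and a spacing of at least 6 ms; rodent scotopic OPs
   recur near 100 Hz (~10 ms apart), so closer maxima are noise bumps, and
   without the spacing rule broadband noise at realistic amplitude
   misnumbers OP3/OP4. Fewer than four detections yield missing values
   (empty cells on disk, never 0).
7. **Eye selection.** Per animal, the eye with the larger b-wave amplitude
   at the brightest flash; ties go to the right eye; a single recorded eye
   passes through.

All steps are deterministic given the input and a fully materialised
configuration (filter spec + windows), which the pipeline writes into its
run log together with a configuration hash.

### Known measurement artifact

The 25 Hz high-pass cannot separate the OP band from the a-wave perfectly:
a realistic a-wave (trough ≈ 15 ms, width ≈ 7 ms) has substantial energy
above 25 Hz, so its filtered residue reaches tens of µV in the 0–40 ms
region for *any* morphology. This is inherent to the filter-based OP
definition, not an implementation defect. Consequences, quantified by the
tests: measured b-wave amplitude is perturbed by < 5 µV in the b-peak
region (> 50 ms); OP implicit times carry a bias ≤ ~0.6 ms; the a-wave is
unaffected because it is measured on the raw average. Injected OP *delays*
are recovered essentially exactly (the leakage background is common to
both conditions).

## Synthetic generator

The waveform model is the minimal composite reproducing scotopic flash
morphology:

    v(t) = s(L)·[ −A_a g(t; 15 ms, 4) + A_b g(t; 55 ms, 8)
                  + A_op e^{−(t−t₀)/τ} sin(2πf(t−t₀))·1[t ≥ t₀] ]
           + drift·t + ε(t)

with unit-peak gamma kernels g(t; tₚ, k) = (t/tₚ)^k e^{k(1−t/tₚ)},
saturating luminance scaling s(L) = I/(I + I₅₀) on linear intensity
(I = 10^L, semisaturation at L = −1.5 log cd·s/m²), and white Gaussian
sample noise ε. Defaults: A_a = 150 µV, A_b = 450 µV, A_op = 40 µV,
f = 100 Hz, t₀ = 18 ms, τ = 25 ms, noise SD 10 µV, drift 0. The kernel
shapes were fixed at design time jointly for morphological plausibility
and so that the OP band sits cleanly above the 25 Hz analysis cutoff —
the generator's purpose is ground-truth recovery, not biophysical
fidelity (no photoreceptor cascade model is implied).

**Ground truth** is computed from the noiseless composite on a 10×
oversampled grid by exhaustive search (trough/peak of the composite and of
its OP-free part; OP peaks of the damped sinusoid, which the tests check
against the closed form argmax = t₀ + arctan(ωτ)/ω + k/f). Ground truth is
therefore invariant to the noise level by construction.

**Cohorts.** A factorial design maps (genotype, treatment) cells to animal
counts. Per-animal multiplicative b-/a-amplitude factors and additive OP
delays are drawn around the cell effect (between-animal SDs: 10%, 10%,
1 ms), each animal gets two eyes with independent 3% amplitude jitter, and
every (cell, animal, eye, luminance, trial) random stream is derived from
the master seed through a fixed spawn-key counter, so any single sweep is
independently regenerable. Identical (design, parameters, seed) give
byte-identical sweep tables.

What the generator does *not* emulate: luminance-dependent implicit-time
shifts, correlated (non-white) instrument noise, blink/movement artifacts,
inter-session drift, and any nonlinear photoreceptor dynamics. Passing
recovery tests therefore demonstrate correctness of the measurement chain
under the stated model, not performance on pathological recordings.

## Statistics

Raw-data one-/two-way fixed-effects ANOVAs are ordinary OLS factorial
fits (statsmodels) summarised with the requested sum-of-squares type.
Unbalanced designs default to Type II with the interaction tested from the
full model; Types I and III (sum-to-zero contrasts) are switchable.

The **summary-statistics ANOVA** consumes per-cell (mean, SEM, n) only.
Within-cell SS is Σᵢ(nᵢ−1)(semᵢ√nᵢ)²; between-cell effect SS come from
weighted least-squares model comparisons on the cell means (weights nᵢ)
with effect coding. Because cell means and variances are sufficient for
the fixed-effects decomposition, the result equals the raw-data ANOVA
*exactly*, balanced or unbalanced — the tests verify agreement to 1e-10
against an independently constructed raw sample, including the published
n = (10, 8, 10, 10) pattern.

Post-hoc comparisons use the residual mean square
(t = Δm/√(MSE(1/n₁+1/n₂)), residual df) with Bonferroni adjustment
p_adj = min(1, m·p). The default family is the four within-row/column
contrasts of a 2×2 design (genotype effect within each treatment, and
vice versa), m = 4; the family is not additionally corrected across flash
luminances, matching per-luminance reporting. Significance stars follow
the */**/***/**** convention at 0.05/0.01/0.001/0.0001.

Degenerate zero-variance inputs return SS = 0, F = NaN (undefined marker)
and p = 1 with a warning rather than raising, so simulation sweeps never
crash. The unpaired t-test is pooled-variance by default with Welch as an
option.

## Assays

* **Dual-luciferase:** net signal = firefly − Renilla (background);
  negative nets are returned but flagged. Group induction is the ratio of
  treated to vehicle mean net signal (means by default; the vehicle mean
  must be positive).
* **qPCR:** technical replicates are averaged per (sample, gene) first;
  ΔCt = Ct_target − Ct_reference per sample; ΔΔCt against the control
  group's mean ΔCt; fold = 2^−ΔΔCt with amplification efficiency fixed at
  2. The reference gene is a parameter (GAPDH and L32 are both common
  choices; neither is privileged). Group comparison is the unpaired t-test
  on per-sample ΔCt. Efficiency-corrected (Pfaffl) models are out of
  scope.
* **Standard curve:** ordinary least-squares line mapping absorbance to
  concentration; readings outside the standard range are flagged as
  extrapolated but still quantified (tissue values can slightly exceed the
  top standard); results are divided by input tissue mass.

## Numerical choices and problem sizes

* Filter: SOS representation; padlen = min(n−1, 3·fs/f_c) samples.
* Tie-breaks: earliest sample for argmin/argmax; right eye on amplitude
  ties.
* Power/type-I simulations run the full synth → filter → extract →
  select-eye chain per animal at the brightest flash (5 averaged trials,
  2 eyes, 10 animals per cell) and test the per-cell b-wave summaries —
  exactly equivalent to the raw-data ANOVA by sufficiency. 200 cohorts for
  the power estimate, 1000 for the type-I rate.
* Parameter recovery uses 100 independent simulated averages of 5 trials.
* The determinism check and the CLI demo run a reduced cohort (2×2, two
  animals per cell, two flash strengths); determinism is size-independent
  and the study-scale cohort is exercised by the `analysis/` drivers.
* Effect magnitudes in the drivers (30% b-wave loss and 5 ms OP delay in
  untreated diabetics, partial rescue under treatment) are free modelling
  choices that reproduce the qualitative published pattern; the published
  figures report significance, not effect sizes.

## Limitations

Single-flash scotopic protocols only (no photopic/flicker, no c-wave, no
ISCEV compliance reporting); no vendor file formats (long-format CSV in,
TSV out); no mixed-effects or repeated-measures models across luminance;
the luciferase analysis assumes unpaired groups. Whether the original
analyses read OP implicit times from the filtered or raw trace is not
specified in the source protocol; this package uses the filtered trace and
makes the choice configurable.
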