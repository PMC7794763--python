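# ergkit

Analysis toolkit for dark-adapted (scotopic) flash electroretinography in
rodent diabetes models, built around the measurement conventions used to
characterise early diabetic retinopathy in the *db/db* mouse: reduced
b-wave amplitude and delayed oscillatory potentials (OPs), with rescue
under fenofibrate treatment. The package provides

* **feature extraction** (`ergkit.signal`) — repeated flash trials are
  averaged per luminance; the a-wave amplitude is measured from the mean
  pretrial baseline to the most negative point of the raw average; OPs are
  isolated with a zero-phase (forward–backward) digital Butterworth 25 Hz
  high-pass filter; the b-wave amplitude is measured from the a-trough to
  the highest point of the OP-subtracted trace; OP1–OP4 implicit times are
  the first four positive peaks of the filtered trace; per animal, the eye
  with the larger b-wave is analysed;
* **a synthetic sweep generator** (`ergkit.simulate`) — gamma-kernel a/b
  lobes plus a damped 100 Hz sinusoid for the OPs, with saturating
  luminance scaling, seeded noise, factorial cohort designs and exact
  ground-truth features for every simulated trace;
* **group statistics** (`ergkit.stats`) — ordinary one-/two-way fixed-
  effects ANOVA with Bonferroni post-hoc comparisons, unpaired t-tests,
  and a two-way ANOVA computed *exactly* from printed per-group summaries
  (mean, SEM, n), balanced or not;
* **assay quantification** (`ergkit.assays`) — dual-luciferase reporter
  induction (firefly − Renilla, vehicle-relative), qPCR relative
  expression by 2^−ΔΔCt with technical replicates averaged first, and
  linear standard-curve readout normalised to tissue mass.

## The core measurement, in brief

For an averaged trace v(t) with stimulus at t = 0 and pretrial baseline
v̄₀ = mean{v(t) : t < 0}:

    a-amp  = v̄₀ − min v(t),           a-implicit = argmin v(t)
    OP(t)  = HP₂₅[v](t)               (order-4 Butterworth, applied
                                       forward and backward → zero phase)
    s(t)   = v(t) − OP(t)
    b-amp  = max_{t ≥ t_a} s(t) − v(t_a)
    OPₖ    = k-th positive peak of OP(t), k = 1..4 (implicit time, µV)

Group comparisons use ordinary two-way ANOVA (genotype × treatment) per
flash strength with Bonferroni-corrected within-row/column contrasts.
Because (mean, SEM, n) are sufficient statistics for the fixed-effects
decomposition, `summary_stats_anova` reproduces the raw-data ANOVA exactly
from a published summary table.

## Worked example

```sh
ergkit all --seed 7 --out results/demo
```

runs simulate → extract → eye selection → ANOVA on a default 2×2 cohort
and writes `sweeps.csv`, `features.tsv`, `features_selected_eye.tsv`,
`anova_report.tsv` and a fully materialised `run_log.json`. The numbered
drivers under `analysis/` run the same stages at study scale; with the
committed seeds they print (abridged):

```
bright-flash b-wave amplitude: median |error| vs ground truth 1.13%
bright-flash OP1 implicit time: median |error| 0.40 ms
  b_amp_uV @ lum 1.4: interaction p=7.28e-05 ****
  op1_implicit_ms @ lum 1.4: interaction p=2.51e-06 ****
  plasma_triglycerides_6mo  genotype p=4.04e-03  treatment p=3.75e-02  interaction p=6.35e-05 ****
luciferase liver : fold 7.62 (injected 8x)
qPCR Acox1 liver : mean fold 3.95, t-test p=4.63e-10
power to detect 30% b-wave reduction (n=10/cell, 200 cohorts): 96.0%
```

i.e. the extraction recovers the generator's ground truth to ~1% on
amplitudes and well under a millisecond on OP timing; the injected
diabetes effect (b-wave loss and OP delay confined to untreated diabetics)
is detected as a genotype × treatment interaction; the re-analysis of the
printed metabolic table recovers the published significance pattern; and
the assay layer returns the injected fold inductions.

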