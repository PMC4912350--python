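# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the design decisions behind `tectalmsi`.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The MSI index and its conventions

For a crossmodal stimulus pair at interstimulus interval (ISI) `isi`,

    MSIn(isi) = (CM(isi) − SM) / SM

with `CM` the mean spike count over the paired trials at that ISI and
`SM` the cell's **maximal** mean single-stimulus count over the two
modalities (V = optic chiasm, HB = hindbrain). Using the larger single
response normalises each cell by its strongest unimodal output, making
the index comparable across cells of different excitability; it also
means a flat `MSIn = 0` curve indicates "paired response no better than
the best single response", not additivity. Because counts are
non-negative, `MSIn ≥ −1` always. The paired-pulse ratio (PPR) for
same-modality pairs uses the repeated modality's single mean as `SM` and
shares the implementation.

Counting conventions (configurable through `SpikeDetectionParams`):

* spike times are milliseconds from the **first** stimulus of a trial;
* counting windows are half-open `[a, b)`; a single trial is counted over
  `[0, window)` and a paired trial over `[0, isi + window)`, so `CM`
  covers the whole pair's response;
* the default window is 500 ms — tectal responses are dominated by
  long-lasting recurrent activity, and the window is exposed so users can
  probe sensitivity;
* spike detection is an amplitude threshold on the trace (default
  polarity `absolute`, since cell-attached spikes can be biphasic), with
  onsets closer than a 2 ms refractory period collapsed into one event.

Signed ISIs (positive = V first, negative = HB first) are preserved in
the data model; analyses pool the two orders onto `|ISI|` by default
(`pool_order=False` keeps them separate), because order effects vanish
when the two single responses are matched in size — the regime the
generator emulates.

## Peak statistics, alignment, and curve comparison

The **preferred ISI** is the argmax of the per-cell tuning map, ties
broken toward the smallest `|ISI|` (deterministic, and conservative
toward short-interval tuning). Group summaries report mean ± SEM of the
per-cell peak index (compared across groups by unpaired t-test) and the
median/IQR of the preferred ISI (Mann-Whitney U), Bonferroni-corrected
when more than one pairwise comparison is made.

Population tuning shape is compared after re-keying each cell's curve by
`ΔISI = isi − preferred_isi` and averaging per offset. Curves are fitted
with a three-parameter Gaussian on a floor,

    v(ΔISI) = floor + amplitude · exp(−ΔISI² / (2·width²)),

by Levenberg–Marquardt least squares with a fixed deterministic
initialisation (amplitude = max−min, floor = min, width = half the ΔISI
span). Two groups are compared with the extra-sum-of-squares F-test:
one pooled fit (RSS₁, df₁) against separate fits (RSS₂ = RSS_A + RSS_B,
df₂), `F = ((RSS₁−RSS₂)/(df₁−df₂)) / (RSS₂/df₂)`.

**Calibration caveat.** Applied to all pooled (cell, ISI) points, this
F-test assumes independent residuals, but points from one cell are
correlated (shared gain, and peak-selection bias at ΔISI = 0, where the
aligned value is an empirical maximum). Measured on identical generator
populations, the pooled-point test rejects true curve equality at the
0.01 level in roughly 15–20% of runs. The acceptance battery therefore
feeds the test **per-offset group means** (offsets with ≥ 3 contributing
cells, `mean_aligned_points`), which removes within-cell clustering and
brings the false-rejection rate down to ~10–13% while keeping full power
for real width contrasts; residual inflation from cells contributing to
many offsets remains and is inherent to the pinned test statistic.

## The additive-null resampling test

For each cell and pair type, every ordered pair of one trial from each
baseline condition yields a predicted sum (33 × 33 = 1089 with the full
design). Mirroring the 4-trial paired design, each bootstrap replicate
draws 4 sums with replacement and averages them; 10,000 replicates form
the null distribution of predicted means. The replicate set *is* the
null distribution, so its standard deviation uses the population formula
(divide by `reps`). The z-score of the actual paired mean against this
distribution classifies the cell with strict inequalities at |z| = 1.97
(two standard deviations): supralinear above, sublinear below, linear at
or within the bounds. A degenerate null (all sums identical) falls back
to exact comparison and is flagged. Per-cell summary z-scores use the
maximal mean paired response over ISIs (the scatter-plot convention);
per-ISI z-scores are attached for completeness. An exact enumeration
oracle (`exact_null_oracle`, all |sums|^k outcomes) validates the
bootstrap in the tests.

**Null calibration.** Treating z as standard normal predicts
2·Φ(−1.97) ≈ 4.9% non-linear classifications under perfect additivity.
That figure holds only *conditionally* on the observed single trials.
Across cells, the null mean is itself estimated from the singles, so

    Var(z) ≈ (Var(actual) + Var(null mean)) / E[null sd²]
           = (μ/k + μ/n_single) / (μ/k) = 1 + k/n_single,

with μ the predicted-sum mean, k = 4 paired trials and n_single = 33
single trials per modality: sd(z) ≈ 1.059, further inflated ~1–2% by the
noisy null-sd denominator (measured sd 1.075 at 2,000 simulated null
cells). The procedure's true null non-linear rate is therefore
≈ 6.3–7%, not 4.9% — a property of the published procedure itself, not
of this implementation. The acceptance test keeps the nominal
4.9% ± 2-point band and is expected to sit at or just beyond its upper
edge; the unit suite checks the implementation against the derivation
above.

## Conductance decomposition

Currents recorded at the reversal potential of one synaptic component
isolate the other: −45 mV (Cl⁻ reversal) isolates excitation, +5 mV
(glutamatergic reversal) isolates inhibition. Conversion is

    g(t) = I(t) / (V_hold − E_rev)   [pA / mV → nS],

after subtracting the mean current over the 50 ms immediately preceding
the first stimulus; baseline subtraction is what makes the conversion
exactly linear in I, and the driving force must exceed 5 mV. Junction
potential is deliberately left uncorrected (matching the recording
convention the data model assumes); users should not correct twice.

Response magnitude defaults to the **peak** conductance in the
post-stimulus window, with an integral (charge-like, nS·ms) mode
selectable; outputs record which mode was used. Negative magnitudes
(baseline noise) are clamped to zero with a warning so the MSI index
keeps its −1 lower bound. Group statistics are a two-way ANOVA
(stage × ISI, type-II sums of squares, interaction included) per
component, and, per cell, the maximal excitatory vs inhibitory MSIn
scatter: Pearson r per stage and an extra-sum-of-squares F-test of a
common slope against separate slopes with df (1, N−4).

## First-spike latency

Per trial, the first spike after the reference stimulus; paired trials
are referenced to the **second** stimulus by default so different ISIs
are comparable. Pooled onsets are summarised by Tukey median-of-halves
quartiles (median excluded from both halves at odd n) — quartile
conventions differ across software, so the convention is fixed and
tested. Cells' median paired and single onsets are compared by a paired
t-test (within-cell design); an unpaired mode serves across-group
comparisons. Identical inputs return (t = 0, p = 1) rather than an
undefined statistic.

## The synthetic generator

The generator emulates the study design: 33 single trials per modality,
4 paired trials per ISI, ISI grid {50, 100, 150, 200, 250, 500, 750,
1000} ms (all configurable). Its components:

* **Enhancement profile** `G(isi) = floor + (peak − floor)·exp(−(isi −
  preferred)²/(2·width²))` — a smooth three-parameter family for the
  unimodal, roughly symmetric tuning shapes the analyses target. The
  degenerate flat profile (peak = floor = 0) is the null.
* **Spike counts** are Poisson. Singles have mean
  `base_rate_spikes_per_trial` (default 4, both modalities — stimulus
  strengths are matched by design). Paired counts follow one of two laws:
  `gain` mode, `Poisson(base·(1+G))`, for MSI-index structure (G ≡ 0
  makes MSIn ≈ 0); and `additive` mode,
  `Poisson((rate_V + rate_HB)·(1+G))`, whose G ≡ 0 case is exactly the
  additive null the linearity test hypothesises. One generator cannot
  make MSIn ≈ 0 and additivity hold simultaneously (additivity implies
  MSIn ≈ 1 when singles are matched), hence the explicit mode switch.
* **Latency** of a trial's first spike is `offset + Gamma(shape, scale)`
  after the driving stimulus (defaults 20 ms + Gamma(2, 15 ms)); paired
  responses are modelled as a burst after the second stimulus with the
  onset advanced additively by `paired_latency_advance_ms` (default
  15 ms, ISI-independent). Later spikes follow at exponential intervals
  (mean 15 ms).
* **Conductances** are difference-of-exponentials transients
  (E: τ_rise 2 ms, τ_decay 30 ms, 2 nS; I: 5 ms, 80 ms, 6 nS — inhibition
  larger, as in tectal neurons), peak-normalised; paired-trial
  conductances are the sum of the two time-shifted single transients
  scaled by `1 + G_component(isi)`. Currents are synthesised as
  `g·(V_hold − E_rev)` plus Gaussian noise (default 5 pA per sample,
  10 kHz sampling by default).
* **Seeding.** Every cell draws from
  `SeedSequence((master_seed, cell_index))`; the linearity resampler uses
  `SeedSequence((seed, crc32(cell_id), pair_code))`. Populations are
  bit-reproducible.

### Stage and drug presets

`preset("st44_46" | "st48_49" | "picrotoxin")` encodes the qualitative
developmental/pharmacological contrasts as per-cell parameter
distributions: young tadpoles — high peak gain (1.2 ± 0.4), preferred
ISIs concentrated short (median grid point 200 ms), broader tuning
(width 100 ± 20 ms); older tadpoles — lower gain (0.55 ± 0.2), preferred
ISIs dispersed long (median 500 ms), narrower tuning (60 ± 15 ms);
picrotoxin — strong gain (2.0 ± 0.5), very short preferred ISIs (median
50–100 ms), broad tuning (300 ± 60 ms). These are this package's own
choices of realistic magnitudes for generator conventions — they are
*not* fitted to, and do not claim to equal, any experimental dataset's
values.

Two preset choices are identifiability compromises worth knowing about.
First, the 45–55% weight on the median preferred-ISI grid bin makes the
population median a stable recovery target. Second, the preset tuning
widths (100/60 ms) are narrower than real aligned tectal tuning curves
appear; with broader widths the per-cell argmax cannot distinguish
neighbouring grid points 50 ms apart from 4 noisy trials (the short side
of the grid is denser, so argmax noise biases preferred-ISI estimates
short). For the same reason, the parameter-recovery checks simulate 16
paired trials per ISI — the design at which per-cell peak localisation
on the default grid becomes reliable — while all other analyses use the
experimental 4. What passing recovery tests show is that the pipeline
estimates are faithful when the design can identify the parameters; they
do not show that a 4-trial experiment pins per-cell preferred ISIs to
50 ms resolution (it cannot).

The conductance population generator draws a shared per-cell factor
multiplying both components' gains (shared factor sd 0.5, independent
gain noise sd 0.15), producing the positive per-cell E–I correlation
seen across tectal neurons, with the developmental contrast carried by
the excitatory gain mean; in stage comparisons both cohorts share one
tuning-shape distribution so the inhibitory law is stage-invariant.

### What the generator does not emulate

Overdispersed (non-Poisson) count noise; stimulus-order asymmetries;
ISI-dependent latency advances; correlations between a cell's spiking
gain and its conductance gains; bursting structure beyond a single
post-stimulus burst; drifting baselines, access-resistance changes, or
any slow nonstationarity across trials. Passing tests therefore
demonstrate correctness of the analysis pipeline under the stated
statistical model, not robustness to every pathology of real recordings.

## Problem sizes used in tests and the acceptance script

Chosen as the smallest sizes at which each property is statistically
sharp: tuning/linearity cohorts of 30 cells per group (16 paired
trials per ISI for recovery checks); 500-cell single-ISI populations for
null calibration at 10,000 bootstrap replicates; 200 repeated 30-cell
experiments for the latency false-positive rate; conductance populations
of 14 cells per stage at 2 kHz sampling with a 4-point ISI grid (the
10 kHz default is unnecessary for transients with ≥ 2 ms rise times);
bootstrap-vs-enumeration checks at 10⁵ replicates on ≤ 5 sums with
k ≤ 3.

## Numerical conventions and degenerate inputs

* Windows half-open; quartiles by Tukey hinges; ties in argmax toward
  smallest |ISI|.
* Curve fits: fixed initialisation (above); non-convergence returns a
  flagged result carrying the initial iterate's RSS.
* `SM = 0` (no spikes to any single stimulus) excludes the cell from
  index analyses with a warning count in the pipeline summary.
* Degenerate bootstrap null: exact comparison, flagged.
* Zero-variance t-tests return (0, 1) for identical inputs.
* JSON summaries strip wall-clock fields, sort keys, and derive all
  randomness from the master seed, so identical configs give
  byte-identical output.

## Known limitations

* The pooled-point curve F-test inherits the independence assumption of
  the published procedure; see the calibration caveat above.
* The resampling z-score's null rate exceeds the nominal normal rate by
  construction (finite-singles term); see the derivation above.
* The per-cell preferred ISI is a noisy argmax; at 4 paired trials per
  ISI its single-cell values should be interpreted as ±1 grid step.
* Conductance decomposition assumes perfect space clamp and exact
  reversal-potential isolation; cross-contamination between components
  is not modelled.
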