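# Methods

## Signal processing model

The pipeline assumes a calibrated tri-axial wrist accelerometer sampled
uniformly in gravitational units. Per sample, the activity-related signal
is ENMO = max(0, ‖a‖ − 1), carried in milli-g throughout; conversion
happens once, at `compute_enmo`. ENMO depends only on the vector norm, so
it is rotation invariant by construction.

Epochs are 60-s arithmetic means anchored at the recording start (not at
clock minutes); a trailing incomplete epoch is discarded rather than
imputed. Days are local calendar days (midnight to midnight); partial
first/last days are kept and subjected to the same validity rule as full
days.

Non-wear detection follows the standard stationarity heuristic for
wrist-worn devices: 60-min windows advancing in 15-min steps; within a
window an axis is stationary when its sample SD < 13 mg **or** its range
< 50 mg; the window is non-wear when at least two of three axes are
stationary; every complete epoch contained in a non-wear window is
excluded from all downstream sums. The published description of this step
names only "default settings" of a widely used R package whose defaults
changed across versions, so the thresholds are exposed in
`PipelineConfig` for auditability rather than hard-coded. Flagging by
window containment makes detection monotone: lengthening a stationary gap
can only flag more epochs. Gravity auto-calibration from the data is
deliberately not implemented — synthetic signals are calibrated by
construction — and the `autocalibrate="none"` config field records the
no-op stage.

Validity: a day is valid with wear ≥ 600 min (inclusive); a subject is
valid with ≥ 4 valid days (inclusive).

## Energy expenditure and intensity

Per epoch, VO₂ = 0.901 · ENMO^0.534 (ml·kg⁻¹·min⁻¹) applied to the
epoch-mean ENMO in milli-g, floored at 3.0 **before** conversion to
MET = VO₂ / 3.5, so the minimum attainable MET is 3.0/3.5 ≈ 0.857.
Intensity boundaries are MET ≤ 1.5 sedentary, 1.5 < MET < 3 light,
3 ≤ MET < 6 moderate, MET ≥ 6 vigorous; in ENMO terms the sedentary
preimage ends near 27.1 mg, light near 99.3 mg and moderate near 363.8 mg
(computed by root finding, never hard-coded).

Daily summaries use the wear-time denominator: category minutes are wear
epoch counts, percentages are relative to daily wear minutes (not 24 h) —
the convention under which the modelled study's sedentary percentages are
consistent with its sedentary minutes and wearing hours. Subject summaries
are unweighted means over valid days only; weekday curves weight every
valid day equally (a subject contributing two Mondays contributes both),
with normal-approximation 95% CIs (mean ± 1.96·SE across contributing
days; cells with one day report missing CIs rather than zero width).

## The synthetic-data generator

The generator stands in for restricted raw data. It emulates, per group
(antipsychotic monopharmacy APM, polypharmacy APP, healthy controls HC):

- **Bout structure.** Wear time alternates among four states
  (sleep/sedentary, light, moderate, vigorous) in a semi-Markov chain.
  Bout lengths are ceil(Exponential(mean)) minutes — geometric, minimum
  one minute — with default means 5/3/2/1 min; the published analysis
  reports no bout structure, and short exponential bouts match the
  fragmented-bout character of wrist data while keeping the
  renewal-process noise of 7-day category fractions near 1–1.5
  percentage points, which is what makes a ±3-point recovery check
  meaningful. States are entered with probability proportional to
  fraction / effective-mean-bout-length, so realised time fractions
  converge to the profile's fractions; bouts carry across midnight
  (per-day truncation measurably biased the sedentary share before this
  was fixed).
- **Epoch ENMO.** Each 60-s simulation epoch draws a target ENMO from the
  state's log-normal distribution (default medians 10/52/190/550 mg,
  sigmas 0.4/0.3/0.25/0.2). Samples in the epoch have vector magnitude
  1 g + target + white noise (SD 2 mg) with a per-epoch uniformly random
  orientation, so `compute_enmo` inverts the construction analytically.
- **Device-off gaps.** One scheduled gap per day (constant gravity-only
  vector), with durations on the 15-min detection grid (base
  105/135/90 min for APM/APP/HC) and grid-aligned start times, so the
  non-wear detector recovers gaps exactly and wearing time is
  22.25/21.75/22.5 h/day against published 22.3/21.7/22.5.
- **Weekend modulation.** Saturday/Sunday scale the light and moderate
  fractions by 0.8, the difference moving into sleep/sedentary —
  matching the published direction of weekday/weekend curves. The
  weekday fractions are inflated so the 5:2 weekly mix returns the
  calibration targets.
- **Calibration.** Group state fractions are obtained from the published
  category minutes/day by solving the state→category "leakage" matrix
  (per-state log-normal band probabilities between the ENMO preimages of
  the MET cut-points) with non-negative least squares, so the *expected*
  pipeline output equals the targets despite distributional spill across
  category boundaries.
- **Between-subject variation.** Per subject: a symmetric truncated
  Gaussian sedentary↔light exchange (SD 0.09 of wear time); mean-one
  Gamma(k, 1/k) multipliers on the moderate and vigorous fractions
  (compensated against sedentary), with group-specific shapes (moderate
  k ≈ 1.1–1.2 for patients, 5 for controls; vigorous k ≈ 0.12–0.3); and
  a ±2-grid-step shift of the daily gap. Every perturbation has zero
  mean, so group means are preserved exactly, while the spread matches
  the published group SDs and the small Gamma shapes reproduce the
  zero-piled moderate/vigorous distributions seen in clinical cohorts —
  the feature that makes patient-vs-control contrasts decisive while the
  two patient regimens remain statistically indistinguishable, as
  published. A single-scale symmetric jitter cannot produce that
  combination at these sample sizes.

The synthetic cohort table draws each patient's drug-class memberships as
independent per-setting Bernoulli variables at the published prevalences
and *derives* the regimen label (none / APM / APP) from the drawn
antipsychotic count, so empirical class frequencies converge to the
configured probabilities. The price of marginal faithfulness is the joint
distribution: real prescribing is strongly negatively correlated through
the near-universal antipsychotic constraint, so the synthetic
any-antipsychotic prevalence sits near 86% rather than the published
97.9%, and combination-cell counts are not expected to match the
published table (the published cells are validated directly through the
Wald-CI layer instead). Counts among class users are 1 + Poisson(0.1–0.2),
landing near the published 1.1–1.2 means.

### What the generator does not emulate

Sleep architecture, posture/angle information, gyroscope and magnetometer
channels, device miscalibration and temperature drift, autocorrelated
within-state intensity, diurnal rhythm beyond the non-wear schedule,
correlated prescribing, dose, depot formulations, and any clinical-scale
trajectories. Passing the round-trip and pattern checks therefore shows
the *pipeline* is correct and the *statistical battery* behaves as
designed under realistic group structure — not that the generator is a
substitute for real wrist recordings.

## Statistics layer

Pearson chi-square without continuity correction (the uncorrected
statistics reproduce the published 0.134 … 235.780 exactly from printed
counts); effect size sqrt(χ²/(N·min(r−1, c−1))) — phi for 2×2, Cramér's V
otherwise (the published r×c "phi" values 0.163/0.136/0.617 are Cramér's
V). Missing data are handled by pairwise deletion per variable, which is
why table Ns vary (607/619/620). Fisher's exact test is the two-sided
hypergeometric tail sum. Mann–Whitney uses midranks, exact enumeration
for n₁·n₂ ≤ 400 without ties, otherwise the tie-corrected normal
approximation. Kruskal–Wallis returns H = 0, p = 1 for all-tied input;
one-way ANOVA raises on all-zero within-group variance. Post hocs are all
pairwise tests with p multiplied by the number of comparisons, capped at
1; Cohen's d uses the (n−1)-weighted pooled SD. The normality screen is a
one-sample Kolmogorov–Smirnov test against a normal with the sample
moments, "normal" iff p ≥ 0.05 (boundary inclusive). The activity report
assigns Kruskal–Wallis to wearing time, mean MET, moderate and vigorous
variables and ANOVA to sedentary and light, as in the modelled analysis;
the assignment is a configurable argument. No global correction is
applied across report rows, mirroring the modelled analysis. Ordering
summaries ("HC<APP/APM") join groups whose Bonferroni-adjusted pairwise p
is ≥ 0.05 with "/" in order of their means.

## Numerical choices

Synthetic samples are float32 (≈ 10⁻⁴ mg quantisation, far below the 2 mg
noise floor, at half the memory traffic); all window sums for the
non-wear variance formula accumulate in float64, because E[x²] − E[x]²
cancels catastrophically otherwise. Classification boundaries are defined
in MET space; the ENMO preimages are irrational and evaluated by Brent
root finding only for reporting and reference computations. Epoch means,
day summaries and subject summaries are exact arithmetic means (no
weighting). Degenerate inputs: empty epoch series aggregate to an empty
frame with a warning; recordings shorter than one window keep all epochs
as wear with a warning; zero-wear days carry missing percentages; cohorts
without patients and ECDFs without wear epochs raise.

## Evaluation protocol and problem sizes

The acceptance tests run five independent replicate cohorts at the
study's group sizes (73/57/114 subjects, 7 days each) and assert the
qualitative group pattern on the **median** Bonferroni-adjusted p across
replicates: at these sample sizes the patient-patient contrasts sit near
the 0.05 boundary by design (the modelled study's own adjusted p-values
for them range 0.07–0.99), so a single simulated cohort occasionally
crosses the line exactly as a single real cohort would, and the median is
the stable summary of what the generator's conditions imply. The
APM-vs-APP non-separability is asserted for sedentary %, moderate %,
vigorous % and mean MET; light is left out because the modelled study's
own adjusted p (0.071) is on the boundary, and the minutes/day variants
are left out because they compound wearing-time differences. Replicate
cohorts are simulated at 2.5 Hz (sampling rate only affects sub-epoch
noise, ~2 mg/√150 per epoch); recovery checks and fixtures run at 10 Hz;
30 Hz is supported by argument. Calibration (group-mean sedentary
minutes within ±5% of targets) is checked on the subjects pooled across
replicates. The rank tests' null rejection rate uses 10,000 seeded
replicates at n = 40 per group.

## Known limitations

- Between-subject wearing-time SD (~0.3 h) is under-dispersed relative to
  the published 0.7–1.0 h, because every gap must stay ≥ 60 min on the
  detection grid to remain recoverable; wearing-time post hocs are
  correspondingly sharper than published.
- The published per-subject Mann–Whitney statistics of the demographic
  tables are not reproducible without raw data and are out of scope; two
  published smoker chi-squares do not follow from their printed counts
  (missing-denominator issue in the source) and are excluded.
- The published combination table's own accounting (rows + clozapine-only
  footnote = 620) leaves no room for the 13 patients without any
  antipsychotic; the package reports both exclusion counts separately and
  makes the partition explicit rather than resolving the source's
  inconsistency.
- A command-line interface is intentionally absent: the numbered analysis
  drivers and the library functions are the interface.
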