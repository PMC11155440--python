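# Methods

## Task and stimulus design

The paradigm is a method of constant stimuli for auditory duration
categorization. A timing range `[d_min, d_max]` with `d_max/d_min = 4`
(one octave on either side of the geometric mean √(d_min·d_max)) is sampled
into 11 durations spaced uniformly in log duration:

    d_i = d_min · (d_max/d_min)^(i/10),  i = 0..10.

Two ranges are built in: sub-second (0.25–1 s, reference 0.5 s) and
supra-second (0.75–3 s, reference 1.5 s). Each duration is presented 4 times
in a seeded random order (44 trials per range); randomization is an
unconstrained permutation of the 4-fold multiset (no constraint on immediate
repetitions — none is part of the protocol). Before testing, four anchor
sounds define the category extremes: the shortest duration twice ("short"),
then the longest twice ("long"). Anchor order is fixed for determinism.
All durations are stored in seconds. Audio rendering of the 500 Hz tone is
out of scope; the package works at the level of trial records.

Note on the published duration lists: the two-decimal printed lists are not
consistently rounded versions of the log-spaced sequence (e.g. 0.2872 is
printed 0.28 but 0.3299 is printed 0.33, and 0.9896 is printed 1). The
package generates the exact log-spaced values; tests assert agreement with
the printed lists to one unit in the second decimal.

## Generative observer model

An observer categorizes duration `d` as "long" with probability

    p(d) = λ/2 + (1 − λ) · Φ((log₁₀ d − log₁₀ PSE) / σ),

parameterized by the point of subjective equality PSE (s), the log₁₀-axis
spread σ, and a lapse rate λ. σ is exposed through the Weber fraction
Wf = 10^(z₇₅·σ) − 1 (z₇₅ = Φ⁻¹(0.75)), the convention used to report
duration-discrimination precision. λ defaults to 0 so the generator matches
the two-parameter fitting model exactly; a nonzero λ exists purely to
stress-test the fitter.

Cohorts are simulated per group and range by drawing

* Wf from a normal distribution truncated below at 0.01 (rejection
  sampling). The floor prevents physiologically implausible step observers;
  for the default group moments it moves well under 1% of the mass. Specs
  whose truncation would remove more than half the distribution are
  rejected.
* PSE from a log-normal with median equal to the group's PSE location and
  coefficient of variation `pse_sd/pse_mean` — multiplicative noise, since
  durations live on a ratio scale and the paradigm is symmetric in log
  duration.

The default cohort (`study_cohort()`) encodes the study conditions this
package models: 22 control-like observers (Wf mean±SD 0.13±0.05 sub-second,
0.14±0.07 supra-second) and 15 DD-like observers (0.24±0.15 and 0.22±0.10),
with identical PSE distributions in both groups (median at the range
reference, CV ≈ 0.2) — the group difference lives in precision only.
Synthetic participant metadata (age ≈ 10–11 y, gender ratios 12F/22 and
8F/15, matched non-verbal z-scores, a math deficit > 2 SD in the DD-like
group, reading deficits in a DD subgroup, reading scores available for
9/22 and 11/15 of participants) emulates the descriptive profile of such a
clinical sample. All randomness descends from a single cohort seed via
`numpy.random.SeedSequence`, so a cohort is fully reproducible from its spec.

What the generator deliberately does not emulate: sequential dependencies,
attention lapses correlated over trials, response times, and trial-level
missingness. Passing tests therefore demonstrate correctness of the
estimation and inference machinery under the stated generative model, not
robustness to every artifact of real child data.

## Psychometric fitting

Responses are tallied per duration and fitted with the two-parameter
cumulative Gaussian in log₁₀ duration by binomial maximum likelihood —
the correct error model for small per-point counts (4 trials per duration).
Numerics:

* log-likelihood accumulated with `log_ndtr` for stability in the tails;
* initialization μ₀ = midpoint of the tested log-range, σ₀ = ¼ of the tested
  log-span; bounds σ ∈ [10⁻³, 2], μ within the tested range ± 0.5;
* L-BFGS-B with objective tolerance 1e−8, plus an always-on multistart: a
  25×25 coarse-grid scan of the likelihood provides a second start, and the
  better of the two solutions is kept. The surface can hold shallow local
  optima at small counts; the test suite enforces equivalence with an
  exhaustive 400×400 grid search to within one grid cell.
* Degenerate data — all responses identical, or step-like sessions whose
  likelihood supremum drives σ to its floor — are returned as flagged
  non-convergent fits with NaN parameters. Downstream stages exclude flagged
  fits and record each exclusion with its reason. At the study design a
  precise observer (Wf ≈ 0.13) produces such sessions roughly 5–6% of the
  time; clamping them would bias group summaries, so they are excluded
  loudly instead.

Derived quantities satisfy PSE = 10^μ, JND = z₇₅·σ, Wf = 10^JND − 1 exactly.
Multiplying all durations by a constant multiplies the PSE by that constant
and leaves Wf unchanged. Nonparametric bootstrap intervals (trial resampling,
percentile bounds) are available; replicates that fail to refit are dropped
and counted, and an interval with > 20% failures is flagged unreliable.

## Group inference

* **t tests** are pooled-variance Student tests (df = n₁ + n₂ − 2), the form
  consistent with the degrees of freedom this literature reports; Cohen's d
  uses the same pooled SD.
* **Bayes factors**: two-sample JZS BF₁₀ with a Cauchy prior (default scale
  r = √2/2) on the standardized effect, computed by one-dimensional
  quadrature over the prior's inverse-χ² mixing variance with the integrand
  evaluated in log space and peak-shifted, so it remains accurate for |t|
  well beyond 12. Reported as log₁₀ BF (LBF); |LBF| thresholds 0.5 / 1 / 2
  label substantial / strong / definitive evidence, with boundary values
  assigned to the weaker category. The prior scale is configurable.
* **Normality**: Shapiro–Wilk (Royston's approximation, via scipy), reported
  as a diagnostic, never used as a gate.
* **Mixed model**: value ~ group + range + group×range (+ participant-level
  covariates) with a participant random intercept, implemented as the exact
  two-stage decomposition of the split-plot design — a between regression on
  participant means (group, covariates) and a within regression on
  between-range differences with effect-coded groups (range, interaction;
  Type III, i.e. unweighted group means under unequal n). On balanced
  complete data this equals the classical split-plot ANOVA to machine
  precision (enforced against direct sums-of-squares formulas in the tests,
  and cross-checked against a REML mixed-model fit). Denominator df
  conventions: between terms N_participants − p_between; within terms
  N_complete − 2. Participants with a single range contribute their
  available measurement to the between part and are excluded, and listed,
  from the within part. Covariates enter as participant-level main effects
  and therefore cancel from within-participant differences; gender is a
  two-level indicator, age and non-verbal reasoning are numeric (z-scores
  are accepted as given; normative conversion is out of scope).
* **Multiplicity**: group comparisons of the two timing ranges use a
  Bonferroni-corrected threshold α/2 (0.025 by default).
* **Power**: smallest per-group n such that the two-sample t test at level α
  reaches the requested power under the noncentral t with noncentrality
  d·√(n/2), by direct search.

## Pipeline and reproducibility

`run_simulation_study` (simulate → fit → infer) and `run_ingest_study`
(read existing trial/metadata tables, optionally through a user-supplied
column map, then the identical downstream) share one analysis path. A
reading index is the mean of word and non-word reading z-scores where both
exist; missing optional metadata downgrades gracefully to a logged omission,
never a silent change. Reports are written as full-precision CSV tables plus
a rounded human-readable summary and a JSON manifest (config echo, seeds,
package version, stage timings). Given identical config and seeds, all
report tables and the summary are byte-identical across runs; only the
manifest's timing entries vary. Ingest uses exact (`round_trip`) float
parsing so re-ingesting a written study reproduces its report bit for bit.

## Problem sizes used in validation

The test suite validates recovery and calibration at the study's own design
(11 durations × 4 reps; 15 vs 22 participants): 200 simulated observers per
group for threshold recovery, 50 replicate cohorts for group separation, and
500 replicate null cohorts (identical group distributions) for the type-I
error of the pooled t test (α = 0.025) and the mixed-model group F
(α = 0.05). Monte-Carlo checks of the response sampler use 10,000 replicate
sessions. These sizes give Monte-Carlo error comfortably below the margins
being asserted while keeping the default test run fast.

## Known limitations

* The fitted model has no lapse parameter (matching the two-parameter
  convention); heavy-lapse observers will inflate fitted σ rather than be
  detected.
* The mixed model supports exactly two groups and two within-levels — the
  design it exists for — not general factorial structures.
* The Weber-recovery estimator carries a small negative bias at 4 reps
  (median ≈ −8 to −10% relative), an inherent property of binomial MLE at
  these counts; it shrinks monotonically with repetitions and is well inside
  the validated 15% envelope.
* Truncated-normal Weber draws make the realized group mean slightly exceed
  the nominal mean when the SD is large relative to the mean (DD-like
  groups); the effect is ≪ 1 SE at the default moments.
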