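# Methods

This note documents the statistical model behind `cogclock`, the defaults
and why they were chosen, and what the synthetic cohort does and does not
emulate.

## Synthetic cohort model

Analyses of cognitive aging cohorts are rarely reproducible from public
data, so the package treats the cohort generator as a first-class,
testable model rather than a fixture. One cohort draw consists of:

- **Ages.** Chronological ages uniform on `[age_min, age_max]`
  (default 19–85 y). Uniform is appropriate for a recruited volunteer
  cohort balanced across the age range; it is not a population age
  pyramid.
- **Latent acceleration.** Each participant carries a latent aging
  acceleration `a ~ Normal(0, accel_sd)` (default SD 5 y), shared across
  all cognitive indices and (partially) with the biological ages. All
  index generation uses the *effective age* = chronological age + `a`.
  The latent values are written to a separate `truth.csv` that no
  analysis stage reads — recovery tests compare against it, the pipeline
  never does.
- **Index series.** Each of the 16 indices is generated per participant
  as `baseline + age_slope·(effective_age − 20) + trait + trial noise`,
  with a stable per-participant trait offset (`between_sd`), Gaussian
  trial noise whose SD may drift with age (`noise_age_slope`,
  heteroscedasticity), and a two-component location mixture
  (`mixture_weight`, `slow_mode_shift`) representing slow
  attentional-lapse responses — the simplest mechanism producing the
  broad, often bimodal trial distributions such tests show. Error
  fractions are `Binomial(k, p)/k` with `p` logistic in effective age,
  which keeps them in [0, 1] with the right mean–variance coupling. An
  optional saturating age response (`response="saturating"`, exponential
  approach with configurable e-folding scale) exists for nonlinearity
  experiments.
- **Biological ages.** Each clock column is
  `intercept + slope·chrono + loading·a + Normal(0, noise)`. The default
  loadings decrease from Phenotypic Age (0.9) through the DNAm clocks to
  GrimAge (0.3), so the acceleration-correlation analysis has a known
  ordering to resolve.

Default effect sizes were set once so that a 118-participant cohort
reproduces the qualitative regime of interest: five indices (CM t+, CM t−,
CM dH+, SM1 ERR-1, SM2 MR) carry strong age trends and the rest weak
ones, individual quantifier–age correlations peak near 0.5, and roughly a
third of the 64 quantifiers clear the BH-0.001 screen. What the generator
does **not** emulate: stimulus-level psychophysics (staircase dynamics),
practice/fatigue effects within a session, non-Gaussian trait
distributions, age-dependent recruitment bias, and any real correlation
structure between distinct tests beyond the shared latent. Passing tests
therefore demonstrate that the *pipeline* recovers structure it is
designed to detect, not that real cohorts contain that structure.

## Quantifiers

SD uses the unbiased (n−1) denominator with the convention SD = 0 for a
single-element series; quartiles use linear interpolation between order
statistics (the common "type 7" rule; no authoritative convention exists
for this kind of data). Empty series yield NA, and participants with NA
in a selected quantifier are dropped per analysis with a logged count.
The shipped default mapping (7 statistics for each of the 8 time-valued
series, one statistic for each of the 8 scalar/count indices) yields
exactly 64 columns; it is a documented stand-in, since 16 indices × 7
statistics over-counts and the authoritative index→statistic assignment
is a free design choice.

## Screening

The Pearson test uses the exact t-transform on n−2 degrees of freedom;
constant columns are flagged degenerate (NA, ranked last) rather than
raising. Benjamini–Hochberg is the classic step-up with cumulative
minimum, capped at 1. Ranking is by adjusted p ascending with ties broken
by raw p then name, for full determinism. The top-k clock search is
restricted to significant quantifiers when at least 5 exist, otherwise it
uses all finite-p quantifiers in rank order.

## Clocks

- **Stratification.** Ages are binned into 7 equal-width bins on
  [10, 90]; ages outside the range are clamped into the boundary bins
  with a log entry. Fold assignment shuffles within each bin and deals
  all participants round-robin through a seeded fold permutation, which
  guarantees overall fold sizes and per-bin fold counts each differ by at
  most one — including bins smaller than the fold count, where an
  off-the-shelf stratified splitter would refuse.
- **Standardization.** Per-quantifier z-scoring is fit on training folds
  only; zero-variance columns are dropped with a log entry.
- **Feature-ranking modes.** `"paper"` ranks quantifiers once on the full
  dataset before cross-validation; this mirrors the common published
  protocol but leaks the held-out folds into the ranking, so reported EVs
  are mildly optimistic. `"strict"` re-ranks inside every training fold.
  `"paper"` is the default for comparability; a dedicated test verifies
  strict mode is not more optimistic on pure-noise data.
- **Objective.** Mean cross-validated EV by default; mean MAE is
  available because minimum-MAE selection is equally defensible and both
  conventions circulate. EV is the shift-invariant
  `1 − Var(residual)/Var(target)` form (identical to scikit-learn's
  `explained_variance_score`); for near-unbiased predictors it is close
  to R².
- **Grids.** Hyperparameter grids are config defaults (regularization and
  RBF width on small log grids, kNN k in 1–25, small forests); published
  work in this area rarely reports exact grids, so these are the
  package's own choices, sized for cohorts of order 10².
- **Tie-breaking.** Equal objective values resolve toward smaller top-k,
  then fewer/smaller hyperparameters, then family name — `select_optimal`
  is a pure function of its inputs.

## Accelerations

Residual mode (default) regresses clock age on chronological age by OLS
and takes residuals, the standard convention in the biological-clock
literature; it makes accelerations mean-zero and uncorrelated with
chronological age, and invariant to any affine recalibration of the
clock. Difference mode (`clock − chronological`) is retained because
group-level statements like "+7 years" read naturally as differences.
Correlation matrices use pairwise-complete rows, which matters when a
biological age is measured on a subset of the cohort only.

## Patterns and groups

The peer reference at age `x` is the Gaussian-weighted mean and SD with
weights `exp(−(age−x)²/(2·7²))`; 7 years is the default kernel SD. The
weighted SD uses the population (Σw-normalized) form — no small-sample
correction is applied, consistent with treating the reference as a
population summary. Each participant is included in its own reference
(weight 1), keeping the moving statistics smooth. The ternary coding uses
a half-SD band with *strict* inequalities; a full-SD band is one
configuration flag away, as both conventions appear in practice.
Directions: times, error fractions and shade-threshold steps are
better-when-smaller; correct-answer counts are better-when-larger.

K-means runs on the {−1, 0, +1} encoding with Euclidean distance, best of
50 restarts by within-cluster sum of squares, k = 7 by default (k is
user-set; no gap-statistic selection). Group letters are assigned
deterministically in descending order of mean per-member "better" count,
so "A" is always the best-performing group. Groups smaller than 2, or
with zero variance, report NA for the one-sample t-test rather than a
fabricated p-value.

## Determinism and seeds

All randomness flows from one config seed. Stages derive their own seeds
as the first four bytes of SHA-256("seed:stage") mod 2³¹, so inserting or
reordering stages never perturbs another stage's draws. Rerunning the
pipeline with the same config reproduces every CSV byte for byte (the
manifest differs only in wall-clock timings).

## Problem sizes used in the automated checks

The test suite exercises the exact-statistics oracles on 1,000 random
instances each, false-positive control on 200 null cohorts of 118×64,
stratification on 100 random cohorts, clock recovery at n = 500,
nonlinearity detection on 20 cohorts of n = 250 with a 12-year saturating
response scale, acceleration recovery on 20 cohorts of n = 200 per
loading, and pattern-group recovery on 25 cohorts of n = 120 with ±15-year
injected subgroups. These sizes give the relevant effects comfortable
statistical margins while keeping a full run of the suite around a
minute.

## Known limitations

- The quantifier mapping and the direction map are configurable stand-ins
  for instrument-specific tables that accompany a given test battery.
- The "paper" ranking mode is deliberately leaky (see above); use
  "strict" for unbiased error estimates.
- Clock artifacts are Python pickles with a version field; they are
  runtime outputs, not an interchange format.
- In-sample clock predictions (used when a final fitted clock is applied
  back to its training cohort) partially absorb noise; cross-validated
  metrics are the honest accuracy measure.
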