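# Methods note

This note records what `labelsurv` computes, the assumptions behind it,
and the reasoning behind every numerical default. It is written from the
package's own perspective; see the README for usage.

## 1. Set-valued classification (LABEL, split-conformal)

**Model.** Let `Y ∈ {1..K}` and let `P̂(y|x)` be any estimated
conditional class-probability function. On a calibration sample
`{(x_i, y_i)}` disjoint from the data used to fit `P̂`, define for each
class `y` the candidate scores `p_i = P̂(y_i | x_i)` over calibration
observations with `y_i = y` (class-`y` count `m_y`). The threshold is

```
t̂_y = min { p_i : #{ j : p_j ≤ p_i } > (m_y + 1)·α_y − 1 },
```

with the count taken tie-inclusively, and the label set of a new point
is `Ĉ(x) = { y : P̂(y|x) ≥ t̂_y }` (inclusive comparison). Sets can be
empty ("null") or contain several labels ("ambiguous"); both are kept.

**Guarantee and assumptions.** If the calibration and evaluation points
are exchangeable within class, then `P(y ∈ Ĉ(X) | Y = y) ≥ 1 − α_y` in
finite samples, regardless of whether `P̂` is any good — a bad estimator
buys its coverage with larger sets. Slight over-coverage of order
`1/(m_y + 1)` is expected. The guarantee needs no model correctness,
only exchangeability and that the fitting and calibration halves are
disjoint (the package enforces the split).

**Numerical choices.** The threshold is always an order statistic of the
calibration scores, never interpolated. At `α_y = 0` it is the class
minimum, so all calibration points of the class are covered. Probability
matrices are validated to be row-stochastic within `1e-8` and
renormalized exactly; worse violations raise.

## 2. Labeling comparators

- **Standard practice**: argmax labels (ties broken toward the lowest
  class index), one pass, Greenwood confidence intervals for survival.
- **Naive bootstrap**: argmax labels fixed per observation; only the
  rows are resampled with replacement.
- **Weighted labeling bootstrap**: rows resampled with replacement; each
  resampled observation receives one label drawn uniformly from its
  conformal label set, uniformly over all `K` classes when the set is
  null. A label is redrawn **independently for every appearance of a
  row in every resample** — duplicated rows in one resample may receive
  different labels. This is the reading that propagates the most label
  uncertainty; it is recorded in the run metadata.

Each resample gets its own child RNG stream spawned from the root seed
(`numpy.random.SeedSequence`), so results are reproducible and do not
depend on execution order or worker count. Point estimates are means
over resamples; intervals are percentile (2.5/97.5 by default).

## 3. Classification metrics

One-vs-rest TP/TN/FP/FN per class, then accuracy, sensitivity,
specificity and PPV per class and macro-averaged with equal class
weight. Zero-denominator measures are reported missing (NaN) rather than
zero — except sensitivity with a nonempty truth class, which is
genuinely 0 when the class is never predicted. Macro averages skip
missing classes with a logged warning. For `K = 3` single-label
predictions the macro accuracy satisfies the exact identity
`macro = (1 + 2·plain)/3`, used as a test oracle. Calibration tables cut
observations into equal-count bins by ordered predicted probability and
compare mean predicted probability with the observed class proportion.

## 4. Survival estimation

Kaplan–Meier product-limit per class stratum, with deaths preceding
censorings at tied times (the standard convention; the risk table is
taken from `lifelines`). The variance is the plain-scale Greenwood
formula

```
Var Ŝ(t) = Ŝ(t)² · Σ_{t_i ≤ t} d_i / (n_i (n_i − d_i)),
```

with the convention that the variance is 0 where `Ŝ(t) = 0`. Intervals
are `Ŝ ± z·SE` clipped to `[0, 1]` — deliberately *not* log-log
transformed, so the interval is interpretable on the probability scale
and matches the bootstrap percentile intervals in units. Summaries per
stratum: median survival (smallest event time with `Ŝ ≤ 0.5`, missing
when never reached), survival at 90 and 365 days. Bias tables compare
predicted-class strata against observed-class strata: median bias in
days, horizon-survival bias in percentage points with a relative-percent
column, and reason codes (`empty_stratum`, `median_not_reached`) instead
of silent zeros. A horizon beyond the last observed time produces the
last step value with a warning only when subjects were still at risk
(genuine extrapolation).

## 5. Synthetic-cohort generator

**What it emulates.** A claims-like cancer cohort where a 3-class label
drives short-term survival: `N = 2000` per replicate, split by
stratified halves into development (≈1000, itself split 500/500 for
fitting/calibration) and validation (≈1000) cohorts.

- **Covariates (15):** 6 standard-normal continuous `c1..c6`; 7
  Bernoulli `b1..b7` with prevalences `(0.5, 0.4, 0.35, 0.3, 0.2, 0.15,
  0.1)`; 2 Poisson counts `n1, n2` with means 1 and 3. Prevalences span
  the range typical of comorbidity flags; the counts mimic utilization
  tallies.
- **Labels:** multinomial logit on two latent contrasts. The *class-1
  contrast* separates class 1 from the rest and is carried by a strong
  block `{c1, c2}` (scale 3.3) plus a medium block `{c3, b2, b3}` (scale
  4.5); the *class-3 contrast* separates class 3 from class 2 and is
  carried by a medium-only block `{c4, n1, b1}` (scale 2.0). Giving the
  rare class no strong predictors is a deliberate design choice: it is
  what keeps class 3 genuinely hard in every scenario. Contrasts are
  centered at the covariate means so that the intercepts
  `(−2.0168, 0, −2.7150)` control the marginal balance directly
  (targets 37/49/13%).
- **Survival:** `T = (−log U · b · e^{−β_y})^{1/a}` with shape `a = 1`
  and scale `b = 90` days — i.e. exponential per class with mean
  `90·e^{−β_y}`. The class effects `β = (0, 0.5, 1.0)` give stratum
  means ≈ 90/55/33 days and were chosen purely for clear stratum
  separation under 365-day administrative censoring (`event` is true iff
  the latent time is ≤ 365). With `β_1 = 0` the class-1 median is
  `90·ln 2 ≈ 62.4` days, used as a closed-form test oracle.
- **Scenarios** share one data-generating process and differ only in
  which covariates the classifier may use: (1) all informative
  covariates — accurate and certain; (2) the medium blocks only, the
  strongest predictors hidden — accurate but uncertain; (3) the
  uninformative covariates plus the weak predictor `b3` — inaccurate and
  uncertain.

**What it does not emulate.** Real correlation structure between
covariates (they are independent), covariate-dependent survival within
class, informative censoring, measurement drift between development and
validation periods, or missing data.

**Calibration.** `calibrate_scenarios` solves the intercepts for the
target balance by fixed-point iteration on a 20 000-point pilot draw
(deterministic given the seed), then selects the three block scales from
a small grid by minimizing squared error against the design anchors
measured on pilot replicates: class balance 37/49/13 (±2 points), naive
macro accuracy ≈ 0.82 in scenario 2 (±0.03), single-label-set shares
≈ 0.75 in scenario 1 and ≈ 0.49 in scenario 2 (±0.05) at `α = 0.10`. The
shipped defaults (`default_config()`) are the frozen output of this
procedure; `labelsurv calibrate` re-runs it.

## 6. Study runner

`run_study` executes `n_reps` replicates per scenario. Per replicate:
simulate; fit the estimator on the full development cohort for the
naive methods and on the first half for the conformal method; calibrate
thresholds on the second half; form sets on validation; run all three
comparators. Per-replicate child seeds come from the root seed, so
results are identical for any `n_jobs`. A replicate failure is recorded
and skipped; the study aborts if more than 1% fail. Summaries report the
across-replicate mean, the across-replicate SD (`mc_se`, the "Monte
Carlo SE" of a single replicate's statistic), and the SE of the mean;
every summary is recomputable from the stored per-replicate records.

**Default problem sizes** (package's own choices, balancing Monte Carlo
error against desk-scale runtime): `n_reps = 1000` and `n_boot = 500`
for a full study; 200 replicates suffice for coverage checks (MC SE of a
coverage mean ≈ 0.001–0.002), and 100 replicates × 50 resamples for
accuracy comparisons (MC SE ≈ 0.2 points). The acceptance script runs
the reduced sizes in ≈ 30 s.

## 7. Open design decisions and limitations

- The class-specific error levels default to a common `α_y = 0.10`; the
  API accepts a vector for asymmetric targets.
- The weighted bootstrap treats the thresholds as fixed once estimated;
  calibration-half variability is not re-bootstrapped. This mirrors the
  intended deployment (thresholds frozen at development time) but means
  the intervals do not account for threshold estimation error.
- Coverage is guaranteed per class marginally, not conditionally on
  `x`; locally the sets can over- or under-cover.
- Null sets are resolved uniformly over all `K` classes, a conservative
  choice that adds label entropy exactly where the classifier abstains.
- The naive comparators' "coverage" is one-shot sensitivity; it is
  reported under the same column for comparability, not because it has
  a coverage guarantee.
- Reported medians become missing under heavy censoring in
  light-mortality strata; downstream bias rows carry reason codes rather
  than imputing.
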