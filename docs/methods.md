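# Methods

## Analysis model

The evaluation is a standard trial-based cost-effectiveness analysis over
a 4-month horizon (no discounting).  Effects are change scores
`E = outcome(T0) − outcome(T1)`, so positive values mean a reduction in
drinking.  Costs are per-participant sums of volume × unit price over
service-use categories, assembled under two perspectives:

* **health-care perspective** — health-care service costs plus the
  per-participant intervention cost;
* **societal perspective** — additionally the intersectoral costs and
  benefits (education, labor & social security, household & leisure,
  criminal justice) and substance-use costs.

The intervention cost is attributed to intervention-arm participants only
(`arm_rule='intervention_only'`; configurable for other designs).  Costs of
alcohol purchases are structurally excluded — alcohol use is the effect
measure, and costing it would double count; the unit-cost table validator
rejects any category whose name contains "alcohol".

Money is carried as exact decimal cents through valuation and rounded only
at output, so costing is reproducible to the cent regardless of platform.
Prices from different price years are indexed to the reference year by the
ratio of index factors; the factors are user-supplied configuration.

### Bootstrap inference

Uncertainty is quantified by a nonparametric bootstrap, resampling
participants with replacement within arm (arm sizes preserved), with
`n_reps = 5000` by default.  Summaries per cell:

* quadrant proportions of the replicate (ΔC, ΔE) cloud on the CE plane.
  Boundary convention (measure-zero for continuous data, fixed for
  reproducibility): ΔE = 0 counts as "not more effective", ΔC = 0 as "not
  more costly", hence (0, 0) → SW.
* the median ICER: 50th percentile (linear-interpolation definition) of
  the per-replicate ratios ΔC/ΔE.  Replicates with ΔE exactly 0 are
  dropped from the ratio and counted (`n_zero_effect_dropped`); when the
  *point* estimate is dominant (ΔE > 0, ΔC < 0) or inferior (ΔE < 0,
  ΔC > 0) the label is reported instead of a number, because a negative
  ratio is not interpretable.  The ratio distribution's cross-quadrant
  pathology is acknowledged; `nmb_summary` provides the net-monetary-benefit
  alternative.
* percentile confidence intervals (plain percentile method, 95% default;
  no Fieller or BCa correction).
* the CEAC, `P(λ·ΔE − ΔC > 0)` over λ from 0 to 1000 € in steps of 10.
  Under this NMB rule `CEAC(0)` equals the SE+SW replicate mass, which is
  close to — but not identical to — the SE share alone whenever SW mass is
  small; both are reported rather than reconciled.

Resampling ignores school clusters by default: the intraclass correlations
of the emulated trial (.01 weekly, .06 binge) are small enough that the
design effect is negligible at its cluster sizes, which is why the original
analysis did not re-estimate effects.  A cluster bootstrap
(`resample='cluster'`: whole schools resampled with replacement within arm)
is exposed for designs where that assumption fails.

Replicate seeds are derived from the configuration seed plus a CRC32 hash
of the outcome (and subgroup label), not the perspective.  Consequences:
switching perspective changes only costs, never the effect replicates, and
adding a subgroup never perturbs any other cell.

### Screening

Exclusion is whole-case and ordered: (1) any answer strictly above its
plausibility limit ("more than" is read as strict, so 120 reported hospital
days in a 120-day recall window is retained and 121 excluded); (2) no
cost answers at baseline.  At follow-up, removal of non-participants
precedes the same two passes.  Stages chain into a flow report whose
percentages use half-up rounding by default; a truncation mode exists
because published flow figures mix conventions.  Cost outliers
(perspective total strictly above €5000 by default) are a sensitivity
scenario, not a base-case exclusion.

### Descriptive statistics

Baseline arm comparisons use the uncorrected Pearson chi-square for
discrete variables and the pooled-variance Student t for continuous ones
(pooled, not Welch, matching the era's default software output; printed t
values from rounded summaries are not exact anchors, whereas chi-squares on
integer counts are).  Cost skewness is diagnosed with the adjusted skewness
G1 over its standard error `√(6n(n−1)/((n−2)(n+1)(n+3)))`; z > 1.96 marks a
right-tailed distribution.  The ICC is estimated by method-of-moments
one-way ANOVA (`s_w² = MSW`, `s_b² = max(0, (MSB − MSW)/n₀)` with n₀ the
imbalance-adjusted mean cluster size), truncating negative between-cluster
components at zero — dependency-free and identical to a mixed model in the
balanced case.

## The synthetic-data generator

`TrialScenario` defaults encode the emulated study's conditions: 17
schools per arm × 78 students (≈2650 at baseline), baseline arm imbalance
in gender, education, religiosity and age, ICC .01 (weekly) and .06
(binge), secular drift of −1.51 glasses/week and −0.33 binge occasions
(drinking increases over the 4 months as part of the sample reaches the
legal drinking age), arm effects 0.73 glasses/week and 0.49 occasions,
~3.5% of participants answering systematically unrealistically (each with
on average ~2.9 implausible fields at ≥1000× the limit), ~2.6%/5.3%
cost-question nonresponse at T0/T1, and ~70% follow-up dropout whose
probability follows a logistic model in mean-centered covariates — missing
not at random by construction.

Choices a user should know:

* **Clusters are balanced and of fixed size.**  Cluster-size variation
  adds nothing the estimators are sensitive to and exact counts make the
  generator's contract easy to state.
* **Clustering enters the outcomes only** (school random intercepts on the
  change scores), not the cost volumes.
* **Volumes** are zero-inflated negative binomial for counts and
  zero-inflated log-normal for hours — both right-skewed with z-scores
  far above 1.96, matching the diagnostic reported for every cost
  category.  Positive-part means were chosen so expected per-category
  costs under the example unit-cost table sit at the scale of a 4-month
  adolescent recall (a few € to a few tens of €).  No distributional
  detail beyond skewness is published, so these are free choices recorded
  in the scenario.
* **Outcome floors.**  T1 outcomes are clipped to their legal range
  ([0, ∞) glasses; [0, 30] binge occasions).  With a baseline mass at
  zero this attenuates the realized arm effect relative to the programmed
  latent effect — visible in the default scenario's binge outcome, where
  ~half the sample starts at zero occasions.  Parameter-recovery tests
  therefore use scenarios whose baselines sit well above the floor, where
  the programmed effect is the truth to recover.  Real questionnaire data
  share this floor behavior; what clipping does *not* emulate is any
  behavioral mechanism behind it.
* **One RNG stream per stage** (structure, demographics, outcomes,
  volumes, response, contamination, dropout), spawned from the scenario
  seed by fixed keys: adding or disabling a stage never changes the draws
  of another, and the same seed reproduces the table bit for bit.

What passing tests on this generator show: the estimators recover known
parameters (ICC to ±0.03 at 200 clusters; 95% CI coverage of the true
incremental effect ≈95% over 200 trials under exchangeability) and the
pipeline's bookkeeping is exact.  What they cannot show: robustness to
real-world features the generator omits — informative cluster sizes,
measurement error correlated across categories, behavioral floor effects,
or MNAR mechanisms other than the logistic model used here.

## Numerical conventions

* Percentiles and CIs: `numpy.quantile(..., method='linear')`.
* Percentage rendering: half-up at configurable decimals (truncation mode
  available); quadrant shares rendered as integers in tables, full
  precision kept in point files.
* Degenerate inputs raise: empty arms, single clusters, constant samples
  for skewness/t, zero margins for chi-square, ΔE = 0 yields an
  "undefined" ICER signal rather than an exception.
* Problem sizes in the test suite are scaled to keep the full run fast
  (hundreds of clusters, thousands of participants, 10–20 seed averages);
  the acceptance script runs the full default scenario (~2650 baseline
  participants, 5000 replications).

## Known limitations

* Complete-case analysis only; no imputation machinery (deliberate, given
  >70% missingness in the emulated setting — but biased under MNAR).
* The participant bootstrap understates uncertainty when ICCs are large;
  use `resample='cluster'` there.
* The packaged unit costs and price-index factors are illustrative
  placeholders, not the published Dutch manual values.
* QALY valuation, regression-based effect adjustment and power
  calculations are out of scope.
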