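# ceatrial

Trial-based cost-effectiveness analysis with intersectoral costs and
benefits, for health economists evaluating prevention programs on
cluster-randomized trial data.

The package grew out of the economic evaluation of a school-randomized,
web-based alcohol-prevention program for adolescents: two arms
(intervention vs. care as usual), outcomes measured as 4-month change
scores (reduction in glasses of alcohol per week; reduction in binge
drinking occasions per 30 days), and costs built from self-reported
service-use volumes valued with unit prices and classified into sectors —
health care plus the intersectoral sectors education, labor & social
security, household & leisure, criminal justice, and substance use.  It
generalizes to any two-arm trial whose costs come from volume x unit-price
valuation.

## What it computes

For arm means `C_i, C_c` (costs under a chosen perspective) and
`E_i, E_c` (mean change scores), the incremental cost-effectiveness ratio

```
ICER = (C_i − C_c) / (E_i − E_c)
```

is the extra cost per extra unit of effect.  Stochastic uncertainty is
handled by a nonparametric bootstrap: participants are resampled with
replacement within each arm (sizes preserved), arm means recomputed, and
the replicate (ΔC, ΔE) pairs located on the cost-effectiveness plane
(NE more effective & more costly; SE dominant; SW less effective & less
costly; NW inferior).  Reported per cell: the 50th percentile of the
replicate ICER ratios, percentile confidence intervals for ΔC and ΔE,
quadrant proportions, and a cost-effectiveness acceptability curve
`CEAC(λ) = P(λ·ΔE − ΔC > 0)` over a willingness-to-pay grid (net monetary
benefit rule).  Note the raw ICER ratio is ill-behaved when replicates
straddle quadrants (a negative ratio is ambiguous between dominant and
inferior); the median ICER is reported as the field's convention and
NMB summaries (`nmb_summary`) are the statistically sound alternative.

Around that core: exact-decimal costing with price-year indexing and a €53
per-participant intervention cost build-up (€7/week tailored-feedback
software over 4 weeks + 2.5 h of participant time valued at €25),
plausibility screening with an auditable participant-flow report (answers
strictly above a limit — e.g. more than 120 hospital days in a 120-day
recall window — exclude the whole case), baseline arm comparisons
(uncorrected Pearson chi-square, pooled t), skewness z-scores, a one-way
ANOVA intraclass-correlation estimator `ρ = s_b²/(s_b²+s_w²)` for
school-level clustering, sensitivity scenarios (cost outliers above €5000
excluded; substance-use costs toggled off), subgroup analyses over
dichotomized background variables, and a synthetic cluster-RCT generator
with known ground truth so the whole pipeline is testable without any
trial data.

## Worked example

```python
from ceatrial import BootstrapCEA, TrialScenario, generate_trial
from ceatrial.config import (default_intervention_spec, default_limits,
                             default_unit_costs)
from ceatrial.scenarios import prepare_analysis_set

scenario = TrialScenario(seed=1)          # study-like defaults
participants, truth = generate_trial(scenario)
aset = prepare_analysis_set(participants, default_limits(),
                            default_unit_costs(), default_intervention_spec())
print(f"analyzed n = {len(aset.data)} (of {len(participants)} at baseline)")

est = BootstrapCEA(n_reps=5000, seed=1,
                   cost_col="cost_societal_perspective",
                   effect_col="weekly_reduction").fit(aset.data)
print(f"delta cost   = {est.delta_cost_:7.2f} EUR")
print(f"delta effect = {est.delta_effect_:7.2f} glasses/week")
print(f"median ICER  = {est.median_icer_:7.1f} EUR per glass/week")
```

prints

```
analyzed n = 746 (of 2652 at baseline)
delta cost   =   93.67 EUR
delta effect =    0.61 glasses/week
median ICER  =   151.5 EUR per glass/week
```

Of 2652 simulated adolescents, 746 survive screening (unrealistic
answers, missing cost answers, ~70% follow-up dropout).  The intervention
arm costs €93.67 more per participant from the societal perspective and
reduces weekly drinking by 0.61 glasses more than control, so buying one
extra glass-per-week of reduction costs about €152 at the median of 5000
bootstrap replications.  Whether that is worthwhile depends on the
willingness to pay; `est.ceac_` gives the probability of cost-effectiveness
across thresholds.

The same pipeline is scriptable from the shell:

```
ceatrial simulate --seed 3 --out sim/
ceatrial report --data sim/participants.csv --reps 5000 --seed 3 --out rep/
```

which writes the flow report, baseline table, per-arm cost summary
(mean, SD, bootstrap median and variance per category), base-case /
sensitivity / subgroup CEA tables, plane and CEAC point files, and a run
manifest with the config hash and seed.

## Configuration

The packaged `data/unit_costs.yaml` is a synthetic example in the style of
the Dutch costing manuals — the published manuals' prices and the official
price-index factors are not reproduced and must be supplied by the user.
`data/limits.yaml` ships the plausibility limits with the 120-day hospital
example preloaded; all limits are user-editable YAML.
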