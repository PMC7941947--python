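# dietcohort

Diet-quality indices and outcome modelling for pregnancy-cohort studies of
child neurodevelopment.

Large birth cohorts ask whether maternal diet quality during pregnancy (and
the child's own early diet) is associated with child ADHD, measured both as a
parent-rated symptom sum and as a registry diagnosis. Answering that question
takes a chain of steps that are usually scattered across ad-hoc scripts:
scoring diet-quality indices from item-level food-frequency data, correcting
for self-selection into the cohort, fitting outcome models that respect the
bounded-count nature of symptom scores, and translating coefficients into
interpretable effect measures. `dietcohort` packages that chain as tested,
composable estimators for epidemiologists and biostatisticians, together with
a seeded synthetic-cohort generator so the whole pipeline can be exercised and
validated without access-restricted registry data.

## What it computes

**Diet-quality indices** (sklearn-style transformers over a subjects × items
grams/day table plus per-item metadata):

- **PDQI** (prenatal diet-quality index, 0–110): twelve components scoring
  adherence to food-based dietary guidelines — fruit, vegetables, whole
  grain, total and fatty fish, red meat, dairy, saturated/trans fat, salt,
  added sugar, and dietary diversity. Adequacy components ramp linearly to
  their maximum at the recommended intake; moderation components hold the
  maximum at or below the limit and decline linearly to zero at twice the
  limit.
- **UPFI** (ultra-processed food index, 0–100): the percent of total energy
  intake contributed by NOVA group-4 items,
  `UPFI = 100 · Σ_NOVA4 (g_j · ED_j) / Σ_all (g_j · ED_j)`.
- **CDQI** (child diet-quality index): the mean of a diversity component
  (share of six main food groups with ≥ 1 daily serving), a quality component
  (signed gram-share of preferred (+1) vs low-nutrient-energy-dense (−1)
  foods), and an equilibrium component (adequacy minus moderation against
  per-group recommendations).

**Inverse-probability-of-participation weighting**: subgroup participation
probabilities `p_g = n_sample,g / n_population,g` over education × 5-year
maternal age band × parity, weights `w_i = 1 / p_g(i)` renormalized to mean 1.

**Outcome models** (MAP / penalized-likelihood estimators with normal(0, 2)
slope priors and Laplace posterior draws for intervals):

- symptom sum `y ∈ [0, 54]`: beta-binomial likelihood with logit-linear mean
  `logit(μ) = Xβ` and scalar precision φ (shapes `a = μφ`, `b = (1−μ)φ`);
- diagnosis `y ∈ {0, 1}`: logistic regression.

Effects are reported per 1 SD of exposure via marginal standardization:
absolute AME `= mean_i[54·μ(x_i + SD) − 54·μ(x_i)]`, relative AME
`= 100 · AME / mean predicted score`, and marginal relative risk
`RR = mean_i p(x_i + SD) / mean_i p(x_i)`, plus a prevalence-extrapolation
curve `prev(k) = baseline · RR^k` for k-SD shifts.

**Validity metrics**: Hedges g known-groups contrasts, omega-total
reliability (principal-axis factoring, promax rotation, Schmid–Leiman
transformation), and Pearson correlations among indices and energy-adjusted
nutrient intakes.

## Worked example

```python
import numpy as np
from dietcohort import GeneratorConfig, generate_cohort, prevalence_curve
from dietcohort.ipw import InverseProbabilityWeighter
from dietcohort.pipeline import fit_outcome_model

cfg = GeneratorConfig(n_population=20_000, seed=1)
sim = generate_cohort(cfg)
sample = sim.cohort[sim.cohort.selected == 1].copy()
sample = InverseProbabilityWeighter(sim.population_margins).fit(sample).transform(sample)
print(f"population n={len(sim.cohort)}, analysis sample n={len(sample)}")

rr = fit_outcome_model(sample, "pdqi", "diagnosis", adjusted=True,
                       rng=np.random.default_rng(2))["effects"]["rr"]
print(f"PDQI, diagnosis (adjusted, IPW): RR per 1 SD = "
      f"{rr.estimate:.2f} (95% CI {rr.lower:.2f}, {rr.upper:.2f})")

res = fit_outcome_model(sample, "pdqi", "symptoms", adjusted=True,
                        rng=np.random.default_rng(2))
a, r = res["effects"]["absolute_ame"], res["effects"]["relative_ame"]
print(f"PDQI, symptoms (adjusted, IPW): AME per 1 SD = "
      f"{a.estimate:.2f} ({a.lower:.2f}, {a.upper:.2f}); "
      f"relative {r.estimate:.1f}% ({r.lower:.1f}, {r.upper:.1f})")

curve = prevalence_curve(sample["adhd_diagnosis"].mean(), rr.estimate, [-3, 0])
print(f"prevalence at -3 SD: {curve['prevalence_pct'].iloc[0]:.1f}% "
      f"(baseline {curve['prevalence_pct'].iloc[1]:.1f}%)")
```

Output:

```
population n=20000, analysis sample n=10083
PDQI, diagnosis (adjusted, IPW): RR per 1 SD = 0.90 (95% CI 0.80, 1.01)
PDQI, symptoms (adjusted, IPW): AME per 1 SD = -0.27 (-0.40, -0.14); relative -3.3% (-4.8, -1.7)
prevalence at -3 SD: 3.6% (baseline 2.7%)
```

Reading this: the synthetic cohort was generated with a per-SD relative risk
of 0.87 and a per-SD symptom shift of −0.28 under education confounding and
education/age/parity-driven participation; the adjusted, weighted chain
recovers both within sampling error at this sample size. The prevalence line
extrapolates the diagnosis risk to a hypothetical population whose mean diet
score sits 3 SD below the sample mean.

The same chain is available from the shell:

```bash
dietcohort simulate --out sim/ --seed 1 --n-population 20000
dietcohort score-indices --intake sim/intake_maternal.csv --metadata sim/food_metadata.csv --which pdqi,upfi
dietcohort weights --cohort sim/cohort.csv --margins sim/population_margins.csv --out sim/weighted.csv
dietcohort fit --cohort sim/weighted.csv --exposure pdqi --outcome diagnosis --adjusted
dietcohort all --out pipeline_out --seed 1 --n-population 5000   # full report bundle
```

## Layout

- `src/dietcohort/indices.py` — PDQI/UPFI/CDQI scorers and component rules
- `src/dietcohort/ipw.py` — participation probabilities and weights
- `src/dietcohort/models.py` — beta-binomial and logistic MAP estimators,
  AME / marginal RR / prevalence curve / stratified fits
- `src/dietcohort/validity.py` — Hedges g, omega total, correlations
- `src/dietcohort/simulate.py` — synthetic cohort generator
- `src/dietcohort/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — modelling assumptions, defaults and limitations
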