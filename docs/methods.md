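# Methods

This note records the modelling choices behind `dietcohort`: what each stage
assumes, which defaults matter, what the synthetic cohort does and does not
emulate, and where the design was genuinely open.

## Diet-quality indices

### PDQI scoring curves

The twelve-component prenatal index is defined by its component
recommendations and maxima (fruit ≥ 250 g/day → 10; vegetables ≥ 250 g/day
→ 10; whole grain ≈ 70 g/day → 10; total fish 300–450 g/week → 5; fatty fish
≥ 200 g/week → 5; red meat ≤ 500 g/week → 10; dairy 3 servings/day → 10;
saturated fat ≤ 10% of energy → 10; trans fat ≤ 1% of energy → 10; salt
≤ 6 g/day, i.e. sodium ≤ 2.4 g/day → 10; added sugar ≤ 10% of energy → 10;
dietary diversity → 10; total 0–110). The published component tables state
recommendations and maxima but not the interpolating curve, so the curve is a
package design decision:

- **Adequacy (minimum-type) components** score `max · min(1, x / threshold)`
  — proportional credit from zero intake up to the recommendation, then
  capped. Proportional scoring of guideline adherence is the standard
  approach in this index family, and a continuous curve is consistent with
  the near-continuous score distributions such indices display in cohort
  data.
- **Moderation (maximum-type) components** hold the maximum at or below the
  limit and decline linearly to zero at twice the limit:
  `max · clip(2 − x/threshold, 0, 1)`.
- **Total fish** is a band (300–450 g/week): proportional ramp below the
  lower edge, full score from the lower edge upward, no penalty above the
  band — the simplest monotone reading of a recommended range. Fatty fish is
  handled the same way above its 200 g/week minimum.
- **Dairy servings** convert grams via 1 serving = 20 g cheese, 2 dl (200 g)
  milk, 125 g yoghurt (150 g for other dairy); the map is a constructor
  argument. The component is scored as adequacy toward 3 servings/day.
- **Dietary diversity** counts distinct items eaten daily (≥ 20 g/day by
  default) within the four major groups (grains, vegetables, fruits, dairy)
  and ramps to its maximum at a configurable ceiling (default 8 items). The
  underlying instrument's exact counting rule is not public; both the
  threshold and ceiling are exposed as parameters
  (`diversity_threshold_g`, `diversity_ceiling`).

All weekly recommendations are converted to g/day internally (÷ 7). Energy
shares are computed from per-item energy density (kJ/g) and per-item
fractions of energy from the relevant nutrient; sodium from mg/g. A subject
with zero total energy cannot be scored (energy-share components are
undefined) and raises an error.

### UPFI

`100 ×` energy from NOVA group-4 items over total energy. NOVA-4 membership
is metadata-driven, never hard-coded: any food list with a `nova_group`
column works. The index is a ratio, hence invariant to uniform rescaling of
intakes (property-tested).

### CDQI

- *Diversity*: `100 × (groups with ≥ 1 daily serving) / 6` over dairy,
  fruits, vegetables, meat, fish, grains; per-group serving sizes are
  configurable (`CdqiRecommendations.serving_g`).
- *Quality*: `100 × Σ(class · grams) / Σ grams` with classes +1 (preferred),
  0 (moderation), −1 (low-nutrient, energy-dense), summed over all items
  including sweets/snacks.
- *Equilibrium*: mean over the six groups of adequacy minus moderation, with
  adequacy `= 100 · min(1, intake / minimum)` and moderation the percentage
  of the group's intake exceeding its upper level
  (`100 · max(0, g − upper) / g`); the component is clipped to [0, 100]
  after averaging. The source instrument's exact adequacy/moderation
  formulas are not public; this is the plainest reading of
  "adequacy − moderation", and the per-group minimum/upper bounds are
  configuration (`CdqiRecommendations`), defaulting to guideline-scale
  values for 3-year-olds.

The total is the arithmetic mean of the three components, by definition.

## Participation weighting

Weights are simple subgroup ratios, not model-based propensities: for each
education level × 5-year maternal age band (≤19, 20–24, …, ≥40) × parity
(0–3) cell, `p_g = sample count / population count` and `w_i = 1/p_g`.
Weights are renormalized to mean 1 over the analysis sample so weighted
likelihoods keep an interpretable effective sample size; the same
normalization is applied inside the model estimators, which also makes any
constant weight vector exactly equivalent to an unweighted fit. A subgroup
present in the sample but empty in the population margins is a hard error —
no trimming or truncation is applied. Age-band edges are configurable; 5-year
bands are a conventional default, as the banding used in the original
population margins is not public.

## Outcome models

The symptom outcome is an 18-item scale scored 0–3 per item, so a bounded
count with `n = 54` trials. It is modelled beta-binomially with a
logit-linear mean and a single precision parameter φ shared across subjects
(shapes `a = μφ`, `b = (1−μ)φ`); overdispersion relative to the binomial is
`1 + (n−1)/(φ+1)`. The diagnosis outcome is Bernoulli with a logit link.

Estimation is maximum a posteriori / penalized likelihood: normal(0, 2)
priors on slope coefficients (the intercept is left unpenalized, and φ is
estimated on the log scale without a penalty — the half-normal prior in the
source family of models applies to random-effect standard deviations, and no
random-effect grouping factor is used here). At cohort sample sizes the
priors are numerically irrelevant; they stabilise small strata. The weighted
objective multiplies each subject's log-likelihood by its (mean-1
normalized) weight. Optimization uses L-BFGS with analytic gradients
(digamma terms for the beta-binomial); the observed information is obtained
by central differences of the analytic gradient (step `1e-5 · max(1, |θ|)`),
and uncertainty is propagated by sampling from the Laplace approximation
N(θ̂, H⁻¹). Intervals on AME/RR are 2.5/97.5 percentiles over (default) 2000
parameter draws; 95% is fixed as the conventional interval level. The
unweighted logistic path is cross-checked against an independent GLM
implementation in the tests; the beta-binomial density is cross-checked
against an independent library density and by brute-force normalization over
all 55 outcomes.

Effect measures use marginal standardization over the analysis sample's
covariate distribution: the exposure enters the models standardized (sample
SD of the model's complete-case sample), so a unit shift is a 1-SD shift of
the raw score. Exposures stay continuous throughout. Relative AME divides by
the mean *predicted* score. The prevalence curve extrapolates
`baseline · RR^k` log-linearly over k-SD shifts (clipped to (0,1) with a
warning), with an optional model-based variant that re-averages predicted
probabilities under shifted exposure. Stratified fits refit the chosen model
per stratum (child sex, maternal ADHD symptom bands) and summarise
homogeneity as pairwise interval overlap; strata below 50 subjects are
skipped and reported.

Complete-case filtering is applied per model to exactly the variables that
model uses; the pipeline logs per-model n (and case counts for the diagnosis
models).

## Reliability and validity metrics

Hedges g is the raw mean difference over the pooled SD
`sqrt(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2))`, with no small-sample correction
factor (the reporting convention followed here states none). Omega total is
computed from a common-factor model: iterated principal-axis extraction,
promax (oblique) rotation, a one-factor solution of the factor correlation
matrix to obtain general-factor loadings γ, Schmid–Leiman residualization
(general loadings `Λγ`, group loadings `Λ·sqrt(1−γ²)` column-wise), and

    ω_t = [ (Σ g)² + Σ_f (Σ λ_f)² ] / V_t ,   V_t = sum of the correlation matrix.

The number of group factors defaults to 3 for ≥ 9 items, 2 for 6–8, 1 for 3–5
(so the three-component child index is scored by a single-factor model, whose
closed form `(Σλ)²/ΣR` is the test oracle). Nutrient correlations are
energy-adjusted (nutrient per MJ) before computing Pearson r.

## Synthetic cohort generator

The generator is the package's test bed and defines its study conditions. It
emulates:

- a 255-item maternal food list and a 36-item child list covering the six
  main food groups plus sweets/snacks, each item carrying food group,
  subtype, NOVA group, quality class, energy density, nutrient-energy
  fractions and sodium;
- log-normal grams/day intakes around realistic group totals, tilted by a
  latent diet-quality trait and a partially independent ultra-processed
  preference (so the adherence index and the processed-energy share
  correlate negatively without being mirror images);
- covariate marginals matching the emulated cohort's descriptive table
  (maternal age 30.2 ± 4.5 y correlated 0.3 with education; BMI 24.0 ± 4.3;
  education distribution ≈ 7/27/42/24%; parity distribution ≈ 45/36/15/4%;
  smoking ≈ 7.6% and declining with education; depression and maternal ADHD
  symptom means 0.25 and 1.1 via clipped gamma draws; 48.9% girls; uniform
  birth quarters; 5.5% sleep problems; total energy ≈ 9.7 ± 2.6 MJ/day);
- outcomes generated from the *computed, standardized* maternal diet score
  z: diagnosis risk `baseline · RR^z · exp(−0.25·c·educ) · quarter factor`,
  mean-pinned to the 2.9% baseline and rejected as a parameterization error
  if any probability leaves (0,1), with a seasonal gradient (fourth-quarter
  births ≈ 45% higher risk than first-quarter); symptoms beta-binomial with
  `logit μ = logit(8.4/54) + b·z − 0.10·c·educ`, where b is chosen so the
  mean score shifts by `effect_ame_per_sd` (default −0.28) per SD of
  exposure, and φ = 7.7 to give a symptom SD near 7.1;
- participation depending **only** on education, 5-year age band and parity
  (`logit p = logit(rate) + s·(0.6·educ + 0.3·ageband − 0.25·parity)`,
  centered covariates), so subgroup ratios identify the selection mechanism
  exactly; `selection_strength = 0` yields a simple random subsample.

Defaults: `effect_rr_per_sd = 0.87`, `effect_ame_per_sd = −0.28`,
`baseline_prevalence = 0.029`, `confounding_strength = 0.5` (moderate
confounding: education shifts the diet latent by 0.5 SD per education SD),
`selection_strength = 1.0` (strong self-selection, ~0.95 PDQI points of
unweighted bias in the mean exposure at default settings),
`selection_rate = 0.5`. Missingness is optional MCAR masking
(`missing_rate`, default 0) over BMI, maternal ADHD, sleep problems and the
symptom score, exercising the complete-case path downstream.

What the generator does **not** emulate — and therefore what passing tests do
not establish about real data: the joint covariate distribution (only
marginals are targeted), instrument measurement error and reporting bias in
food frequencies and symptom ratings, informative (non-MCAR) missingness,
longitudinal attrition structure beyond a single selection event, sibling
clustering, and any real food-composition database (item metadata are
synthetic draws around plausible group-level values). Index-score
distributions are matched only roughly (means within a few points, SDs
within ~20%); no attempt is made to reproduce them exactly.

## Numerical choices and degenerate inputs

- Mean probabilities are clipped to `[1e-10, 1−1e-10]` inside the
  beta-binomial objective; predicted-probability pile-up at the boundary
  (> 1% of fitted values within 1e-6 of 0/1) flags possible separation with
  a warning.
- `standardize` requires ≥ 2 distinct values and raises on constant input;
  SDs use ddof = 1 throughout.
- Omega requires a positive-definite correlation matrix and ≥ 3 components;
  factor orientation fixes each loading column's sum to be positive, and
  general-factor loadings are clipped to [0, 1] before residualizing.
- Interval endpoints are widened, if necessary, to bracket the point
  estimate (finite-draw percentile jitter).
- Reports round estimates to 2 decimals and percentages to 1.

## Problem sizes

The bundled tests run the recovery chain on a population of 60,000 (analysis
sample ≈ 30,000) and the calibration checks on populations of 100,000–120,000;
the end-to-end pipeline example uses 3,000–20,000 subjects. These sizes were
chosen so every Monte-Carlo assertion has comfortable power while the whole
suite stays fast on a single CPU.

## Known limitations

- MAP + Laplace intervals are asymptotic; no MCMC mode is shipped. At the
  sample sizes used here the normal approximation is excellent for both
  models, but small-stratum intervals should be read cautiously.
- The AME/RR intervals ignore uncertainty in the exposure SD (it is treated
  as known, matching the per-1-SD reporting convention).
- Random-effect terms are not implemented; no grouping factor is defined in
  the analysis this package operationalises.
- The prevalence curve's closed form assumes a constant per-SD RR across the
  whole exposure range; the model-based variant relaxes this only within the
  logistic model's functional form.
- IPW corrects selection on education × age band × parity only; selection on
  unmeasured variables is out of scope, as is model-based propensity
  estimation.
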