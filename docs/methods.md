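# Methods

## Index scoring

Each of the eight components is a clamped linear ramp between a zero-point
and a full-point cutoff; adequacy components (fruits & vegetables, fibre,
fish) rise with intake, moderation components (red meat, SFA, sodium, SSB,
added sugar) fall.  Decisions where the cutoff table alone is ambiguous:

- **Boundary values score by the interpolation endpoints.**  The ramp is
  continuous, so sodium at exactly 2.4 g/day scores 0, red meat at exactly
  500 g/week scores 0, and red meat at exactly 200 g/week scores 10.  This
  is the unique continuous reading of "≤/>" cutoffs combined with linear
  scoring.
- **The fruit/vegetable halving rule applies after clamping**, so the
  maximum attainable score with fruit > vegetables is 5 points.
- **E% components.**  SFA and added sugar are scored on the percentage of
  total energy they contribute.  Gram masses are converted with Nordic
  energy factors — fat (hence SFA) 37 kJ/g, carbohydrate (hence added
  sugar) 17 kJ/g — exposed per rule so kcal-based Atwater factors can be
  swapped in.  Profiles carrying precomputed E% fields are supported via a
  flag (`precomputed_energy_percent`); the gram-mass route is the default.
- **Absolute intakes, no energy standardisation.**  Intakes are scored as
  consumed, not rescaled to a 10 MJ/day reference, even though the
  underlying guidelines are phrased per 10 MJ.  Users comparing groups with
  very different energy intakes should be aware the index partly reflects
  quantity.
- **Units.**  Fish, red meat and SSB cutoffs are weekly; the readers
  multiply g/day columns by 7 when the schema declares daily units.  SSB
  millilitres are treated as grams (beverage density ≈ 1).  Under linearity
  it is immaterial whether the fish cutoff is evaluated weekly or as the
  daily equivalent 50 g/day.

Invalid rows (negative intake, non-positive energy where an E% component is
scored) raise, or with `on_error="skip"` are dropped and listed — never
silently zeroed.

## Cohort pipeline

- **Exclusions** are applied in a declared order (implausible energy
  <2,500 or >25,000 kJ/day on the follow-up FFQ, multiple births, offspring
  age ≥15) with each row tallied once under the first rule it violates, so
  the tally reads like a flow chart.  A sensitivity set (maternal energy
  <6 MJ/day; BMI ≤18.5 or missing; vegetarian) is also registered.
- **Quartiles** use the 25th/50th/75th empirical percentiles (linear
  interpolation of order statistics) of the post-exclusion analysis sample;
  values exactly at a cutpoint go to the lower quartile.  Re-running on the
  same scores is bit-identical.  All-equal scores raise a degenerate-rank
  error.
- **Imputation** is single-value: median for maternal age, mode for
  smoking, physical activity and parity, an explicit "missing" category for
  prepregnancy BMI.  Covariates more than 50% missing (configurable) warn.
- **Risk model.**  Binomial GLM with log link (statsmodels), warm-started
  at the closed-form proportion-ratio solution; Wald CIs on the log scale.
  For the unadjusted single-factor model the MLE coincides with the
  observed-proportion ratio, which the tests exploit as an independent
  closed-form oracle.  Non-convergence (common for log-binomial models with
  many covariates) triggers a Poisson working model with HC1 sandwich
  variance, flagged `fallback_used`.  An exposure cell with zero (or only)
  cases raises a separation error naming the group rather than returning an
  unbounded estimate.
- **Trend test**: the quartile factor is replaced by one continuous term
  holding the within-quartile median of the exposure score (computed on the
  analysis sample, not printed group means); two-sided Wald p.
- **Correlations**: Pearson where a config map flags both variables
  approximately normal, Spearman otherwise; constant inputs raise.
- **Attrition comparison**: one-way ANOVA / mean difference with 95% CI for
  continuous characteristics, chi-square (no continuity correction) with
  small-expected-cell warnings for categorical ones.
- **Continuous association**: OLS of offspring on maternal score
  (optionally + covariates), slope rescaled per 10 maternal points, R²
  reported.  Both unadjusted and adjusted variance explained are reported;
  no single "variance explained" figure is targeted because the unadjusted
  r² (≈5% at r = 0.22) and a covariate-adjusted model R² are different
  quantities.
- No multiple-testing correction anywhere; raw two-sided p-values,
  0.05 threshold.  The sex-interaction check is a joint Wald test of
  exposure×sex product terms in model B.

## Synthetic cohort generator

The generator emulates FFQ-derived intakes for 19,582 mother–offspring
pairs (or 21,082 with the study-flow exclusion preset):

- **Marginals** per component are lognormal (parameterised by published
  median and IQR) for right-skewed intakes — fruit & veg, fish, red meat,
  SSB, added-sugar E%, offspring fibre — and zero-truncated normals (mean,
  SD) otherwise.  Energy is truncated to the plausible window
  [2,500, 25,000] kJ/day because the published summaries describe the
  post-exclusion sample; implausible values enter only by explicit
  injection.  Fruit and vegetables are generated combined and split with a
  random vegetable share ~ N(0.5, 0.08), so the halving rule genuinely
  fires for roughly half the subjects.
- **Joint structure** is a Gaussian copula: component normal score =
  λ·Z + √(1−λ²)·ε with Z the subject's latent quality.  Loadings are signed
  by direction and ordered like the published component-versus-total
  correlation panel; sodium and energy load ≈0, matching their near-zero
  printed correlations.
- **Correlation calibration.**  Clamped piecewise-linear scoring attenuates
  correlation, so the latent pair correlation is set to
  ρ_latent = ρ_target/(a_m·a_o), a = corr(total, Z) estimated on a 40,000-
  subject internal sample, then corrected once multiplicatively against an
  end-to-end measurement.  The calibration uses a fixed internal seed, so
  it is a deterministic property of the configuration (cached per config)
  and adds no per-run noise; user seeds control only the cohort draw.  At
  the defaults this yields ρ_latent ≈ 0.39 and recovers Pearson r within
  ±0.01 of 0.22 at n = 19,582.
- **Score moments.**  The component marginals, not the score moments, are
  the primitive: scoring the defaults yields totals with mean ≈ 23 and SD
  ≈ 8.5–9.5 per generation, close to the published 23.5 (7.4) and 24 (9)
  without a separate moment-matching loop.  The direct bivariate-normal
  score path (`simulate_bivariate_scores`) uses exact means/SDs 24/7 and
  24/9 for statistical-property work.
- **Covariates** interpolate the published bottom-to-top-quartile
  characteristics linearly in the latent-quality percentile (older, leaner,
  more educated, more active, less smoking, longer lactation at higher
  quality), with sporadic missingness at the published rates (age 0.02%,
  BMI 4.7%, others ~1%).  Participation follows a logistic model with
  planted education/age/BMI/sex effects for attrition-recovery tests.
- **Exclusion injection** plants values that genuinely violate the filters
  (energy outside the plausible window, a multiples flag, age ≥15) in
  disjoint randomly chosen rows, so the exclusion tally is driven by the
  filters, not hidden labels.

**What passing tests do and do not show.**  The generator reproduces
published marginal summaries, one cross-generation correlation, and smooth
monotone covariate gradients.  Real FFQ data have features it does not:
reporting error correlated with adiposity and social desirability, item-level
granularity, heaping, non-monotone covariate patterns, and attrition
mechanisms beyond a logistic model.  Recovery of planted effects therefore
validates the pipeline's statistics, not the substantive findings on any
real cohort; adjusted-model estimates on real data are not desk-reproducible
from published summaries alone.

## Numerical choices and problem sizes

- GLM: IRLS, max 200 iterations, statsmodels defaults otherwise;
  z-quantile 1.959964 for CIs.
- Quartile ties: lower quartile; percentile definition: linear
  interpolation.
- Analytic quartile-concordance oracle: bivariate-normal rectangle
  probabilities via scipy's MVN CDF; RR(ρ=0.22) = 2.0765.
- Test problem sizes: shared fixture cohort n = 4,000; recovery checks at
  n = 10,000–19,582; trend null calibration 500 replicates of n = 1,500
  (type-I error 5% ± 2%); randomized scorer property checks at 12,000
  intakes per component.  Sizes chosen to keep Monte-Carlo error well below
  the tolerance being asserted.

## Known limitations

- Single-value imputation understates covariate uncertainty (by design,
  mirroring the analysis it implements); no multiple imputation.
- The log-binomial/Poisson fallback changes the variance model; flagged but
  not bridged by any small-sample correction.
- The copula's higher-order dependence (tail behaviour, component-pair
  correlations beyond the latent factor) is a modelling convention, not
  estimated from data.
- No causal mediation, survey weighting or longitudinal growth modelling.
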