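# dkhei

Danish Healthy Eating Index (HEI) scoring and mother–offspring diet-quality
cohort analysis, with a synthetic two-generation FFQ-intake generator so the
whole pipeline runs and is validated without any restricted data.

## The problem

Does a mother's diet quality during pregnancy predict her child's diet
quality years later, when the adolescent increasingly makes their own food
choices?  Answering this requires (i) a diet-quality index that condenses
food-frequency-questionnaire (FFQ) intakes into a single guideline-adherence
score for both generations, and (ii) a regression framework that expresses
the mother–offspring association as interpretable relative risks.

This package implements both pieces for the Danish setting:

**The index.** Eight components — fruits & vegetables, dietary fibre, fish,
red meat, saturated fatty acids (SFA), sodium, sugar-sweetened beverages
(SSB), added sugar — each scored continuously on [0, 10] by linear
interpolation between a zero-point and a full-point cutoff taken from the
Danish food-based dietary guidelines (foods) and the Nordic Nutrition
Recommendations (nutrients):

| component | 0 points | 10 points | basis |
|---|---|---|---|
| fruits & vegetables | 0 g/d | ≥600 g/d (½ vegetables)¹ | g/day |
| dietary fibre | 0 g/d | ≥30 g/d | g/day |
| fish | 0 g/wk | ≥350 g/wk | g/week |
| red meat | >500 g/wk | ≤200 g/wk | g/week |
| SFA | ≥10 E% | 0 E% | % of energy |
| sodium | >2.4 g/d | ≤1.6 g/d | g/day |
| SSB | >500 g/wk | 0 g/wk | g/week |
| added sugar | ≥10 E% | 0 E% | % of energy |

¹ if fruit exceeds vegetables the component score is halved.

The component scores sum to a total on [0, 80].  E% is computed as
100 · mass[g] · (kJ/g) / energy[kJ] with Nordic factors (fat 37, carbohydrate
17 kJ/g).

**The model.** Both scores are quartiled on the analysis sample; the outcome
is the offspring landing in the top quartile of their own score.  A
log-linear binomial GLM estimates RR(Q2..Q4 vs Q1) with Wald 95% CIs; the
trend test recodes quartiles by their within-quartile median score.
Adjustment sets: model A (maternal age, prepregnancy BMI category, parity,
education, lactation, physical activity, alcohol, smoking), model B (A plus
offspring sex and energy-intake quartile).  When the log-binomial fit fails
to converge the model falls back to Poisson regression with robust sandwich
errors and flags it.

## Worked example

```python
import numpy as np
from dkhei import GeneratorConfig, QuartileRiskModel, simulate_pairs

cohort, truth = simulate_pairs(GeneratorConfig(n_pairs=19_582), seed=1)
print("r =", round(np.corrcoef(cohort.maternal_hei, cohort.offspring_hei)[0, 1], 3))
print(QuartileRiskModel.from_cohort(cohort).fit().summary())
```

prints

```
r = 0.222
Quartile risk model (unadjusted)
==========================================================
Q          cases/N      RR            95% CI
Q1        842/4896    1.00
Q2       1074/4895    1.28      (1.18, 1.38)
Q3       1271/4895    1.51      (1.40, 1.63)
Q4       1709/4896    2.03      (1.89, 2.18)
p for trend: <0.001
```

The generator planted a latent mother–offspring diet-quality correlation of
0.22; scoring the generated intakes recovers r = 0.222, and offspring of
top-quartile mothers are about twice as likely to be top-quartile
themselves (RR ≈ 2.0) — the quartile-concordance implied by a bivariate
normal at that correlation (analytic value 2.08).  Fitting published
per-quartile counts instead reproduces printed results exactly:

```python
res = QuartileRiskModel.from_counts((812, 1080, 1292, 1726),
                                    (4879, 4948, 4898, 4857)).fit(with_trend=False)
print(res.rr.round(2).to_dict())
# {'Q1': 1.0, 'Q2': 1.31, 'Q3': 1.58, 'Q4': 2.14}
```

A `dkhei` command-line tool exposes `score`, `simulate`, `fit`, `attrition`
and `reproduce-tables` (the last refits all bundled published count tables
and exits non-zero on any mismatch).

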