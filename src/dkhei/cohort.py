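"""Cohort-level operations: exclusions, quartiles, imputation, correlation,
attrition comparison.

The cohort is a pandas DataFrame with one row per mother-offspring pair.
Expected columns (all optional except those an operation needs):

``pair_id``; ``maternal_hei``, ``offspring_hei`` (points);
``maternal_age`` (years), ``prepregnancy_bmi`` (kg/m2),
``prepregnancy_bmi_cat`` (underweight/normal/overweight/obese/missing),
``parity`` (0/1/2+), ``education`` (high/medium/skilled/unskilled),
``lactation`` (<=1m/2-6m/>=7m), ``physical_activity`` (low/high),
``alcohol`` (yes/no), ``smoking`` (never/occasionally/daily);
``offspring_sex`` (girl/boy), ``offspring_age`` (years),
``offspring_energy`` (kJ/day), ``offspring_bmi_cat``;
``multiple_birth`` (bool), ``vegetarian`` (bool), ``participated`` (bool).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExclusionRule",
    "EXCLUSION_RULES",
    "PRIMARY_EXCLUSIONS",
    "SENSITIVITY_EXCLUSIONS",
    "DegenerateQuartileError",
    "apply_exclusions",
    "assign_quartiles",
    "impute_covariates",
    "correlate",
    "CorrelationResult",
    "attrition_compare",
    "AttritionReport",
]


# ---------------------------------------------------------------------------
# Exclusions

@dataclass(frozen=True)
class ExclusionRule:
    """A named row filter: ``predicate(df)`` marks rows to drop."""

    name: str
    describe: str

    def mask(self, df: pd.DataFrame) -> pd.Series:  # pragma: no cover - abstract
        raise NotImplementedError


class _Predicate(ExclusionRule):
    def __init__(self, name, describe, fn):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "describe", describe)
        object.__setattr__(self, "_fn", fn)

    def mask(self, df: pd.DataFrame) -> pd.Series:
        return self._fn(df).fillna(False).astype(bool)


def _implausible_energy(df, low=2500.0, high=25000.0, col="offspring_energy"):
    e = pd.to_numeric(df[col], errors="coerce")
    return (e < low) | (e > high)


#: Registry of exclusion rules by name.
EXCLUSION_RULES: dict[str, ExclusionRule] = {
    "implausible_energy": _Predicate(
        "implausible_energy",
        "total energy intake <2,500 or >25,000 kJ/day",
        _implausible_energy,
    ),
    "multiple_birth": _Predicate(
        "multiple_birth", "multiple pregnancy or birth",
        lambda df: df["multiple_birth"].astype(bool),
    ),
    "age_ge_15": _Predicate(
        "age_ge_15", "offspring age >= 15 years",
        lambda df: pd.to_numeric(df["offspring_age"], errors="coerce") >= 15,
    ),
    # sensitivity set
    "low_maternal_energy": _Predicate(
        "low_maternal_energy", "maternal energy intake <6.0 MJ/day",
        lambda df: pd.to_numeric(df["maternal_energy"], errors="coerce") < 6000.0,
    ),
    "low_or_missing_bmi": _Predicate(
        "low_or_missing_bmi", "prepregnancy BMI <=18.5 kg/m2 or missing",
        lambda df: (pd.to_numeric(df["prepregnancy_bmi"], errors="coerce") <= 18.5)
        | pd.to_numeric(df["prepregnancy_bmi"], errors="coerce").isna(),
    ),
    "vegetarian": _Predicate(
        "vegetarian", "vegan/vegetarian mother",
        lambda df: df["vegetarian"].astype(bool),
    ),
}

#: Primary study-flow exclusions, in the order they are tallied.
PRIMARY_EXCLUSIONS: tuple[str, ...] = ("implausible_energy", "multiple_birth", "age_ge_15")

#: Sensitivity-analysis exclusion set.
SENSITIVITY_EXCLUSIONS: tuple[str, ...] = (
    "low_maternal_energy", "low_or_missing_bmi", "vegetarian",
)


def apply_exclusions(df: pd.DataFrame,
                     rules: tuple[str, ...] = PRIMARY_EXCLUSIONS,
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows failing any exclusion rule; tally by first matching rule.

    Rules are applied in the given order and each excluded row is counted
    once, under the first rule it violates, so the tally reproduces a
    flow-chart style accounting.

    Returns the filtered table and an ordered ``{rule: count}`` tally with an
    extra ``"remaining"`` entry.
    """
    unknown = [r for r in rules if r not in EXCLUSION_RULES]
    if unknown:
        raise KeyError(f"unknown exclusion rule(s): {unknown}; "
                       f"known: {sorted(EXCLUSION_RULES)}")
    tally: dict[str, int] = {}
    already = pd.Series(False, index=df.index)
    for name in rules:
        m = EXCLUSION_RULES[name].mask(df)
        tally[name] = int((m & ~already).sum())
        already |= m
    out = df.loc[~already].copy()
    tally["remaining"] = int(len(out))
    return out, tally


# ---------------------------------------------------------------------------
# Quartiles

class DegenerateQuartileError(ValueError):
    """All scores identical: quartile ranking is undefined."""


def assign_quartiles(scores, labels=("Q1", "Q2", "Q3", "Q4")):
    """Assign empirical quartiles Q1..Q4 to a score vector.

    Cutpoints are the 25th/50th/75th percentiles (linear interpolation of
    order statistics) of the non-missing scores.  Values exactly at a
    cutpoint go to the lower quartile.

    Returns ``(labels, cutpoints)`` where labels is a pandas Categorical
    aligned with the input (NaN scores yield missing labels).
    """
    s = pd.Series(np.asarray(scores, dtype=float))
    valid = s.dropna()
    if len(valid) < 4:
        raise ValueError("need at least 4 non-missing scores to form quartiles")
    if valid.nunique() == 1:
        raise DegenerateQuartileError("all scores are identical; cannot rank into quartiles")
    cut = np.percentile(valid, [25, 50, 75])
    idx = np.full(len(s), -1)
    ok = s.notna().to_numpy()
    idx[ok] = np.sum(s.to_numpy()[ok, None] > cut[None, :], axis=1)
    lab = pd.Categorical.from_codes(idx, categories=list(labels), ordered=True)
    return lab, cut


# ---------------------------------------------------------------------------
# Imputation

#: Default single-value imputation plan for model covariates.
IMPUTATION_PLAN = {
    "maternal_age": "median",
    "smoking": "mode",
    "physical_activity": "mode",
    "parity": "mode",
    "prepregnancy_bmi_cat": "missing_category",
}


def impute_covariates(df: pd.DataFrame,
                      plan: dict[str, str] = IMPUTATION_PLAN,
                      warn_fraction: float = 0.5,
                      ) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Fill missing model covariates by median/mode or a 'missing' category.

    Maternal age is imputed with the sample median; smoking, physical
    activity and parity with the sample mode; prepregnancy BMI category
    gains an explicit ``"missing"`` level.  Covariates missing in more than
    ``warn_fraction`` of rows trigger a warning (never silent).

    Returns the imputed table and a log ``{covariate: {n_missing, fill}}``.
    """
    out = df.copy()
    log: dict[str, dict] = {}
    n = len(out)
    for col, how in plan.items():
        if col not in out.columns:
            continue
        miss = out[col].isna()
        n_miss = int(miss.sum())
        if n and n_miss / n > warn_fraction:
            warnings.warn(
                f"covariate {col!r} is missing in {n_miss}/{n} rows "
                f"(> {warn_fraction:.0%}); single-value imputation is dubious",
                stacklevel=2,
            )
        if how == "median":
            fill = float(pd.to_numeric(out[col], errors="coerce").median())
        elif how == "mode":
            fill = out[col].mode(dropna=True).iloc[0]
        elif how == "missing_category":
            fill = "missing"
        else:
            raise ValueError(f"unknown imputation method {how!r}")
        if n_miss:
            if isinstance(out[col].dtype, pd.CategoricalDtype) and fill not in out[col].cat.categories:
                out[col] = out[col].cat.add_categories([fill])
            out.loc[miss, col] = fill
        log[col] = {"n_missing": n_miss, "fill": fill}
    return out, log


# ---------------------------------------------------------------------------
# Correlations

@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    method: str
    r: float
    p: float
    n: int


def correlate(df: pd.DataFrame,
              pairs: list[tuple[str, str]],
              method_map: dict[str, str] | None = None,
              default_method: str = "spearman") -> list[CorrelationResult]:
    """Pearson/Spearman correlations for a list of variable pairs.

    ``method_map`` assigns ``"pearson"`` to variables judged approximately
    normal; all other pairs use ``default_method``.  A pair uses Pearson only
    if both variables are flagged pearson.  Two-sided p-values.
    """
    method_map = method_map or {}
    results = []
    for x, y in pairs:
        sub = df[[x, y]].dropna()
        if len(sub) < 3:
            raise ValueError(f"pair ({x}, {y}): need >=3 paired observations")
        xv, yv = sub[x].to_numpy(float), sub[y].to_numpy(float)
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            raise ValueError(f"pair ({x}, {y}): constant variable, correlation undefined")
        method = ("pearson"
                  if method_map.get(x) == "pearson" and method_map.get(y) == "pearson"
                  else default_method)
        if method == "pearson":
            r, p = stats.pearsonr(xv, yv)
        else:
            r, p = stats.spearmanr(xv, yv)
        results.append(CorrelationResult(x, y, method, float(r), float(p), len(sub)))
    return results


# ---------------------------------------------------------------------------
# Attrition

@dataclass(frozen=True)
class AttritionRow:
    characteristic: str
    kind: str                       # continuous | categorical
    summary: dict
    p: float
    warning: str | None = None


@dataclass
class AttritionReport:
    n_participants: int
    n_nonparticipants: int
    rows: list[AttritionRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {"characteristic": r.characteristic, "kind": r.kind, "p": r.p,
                   "warning": r.warning}
            rec.update({k: v for k, v in r.summary.items()
                        if not isinstance(v, dict)})
            recs.append(rec)
        return pd.DataFrame(recs)


def attrition_compare(df: pd.DataFrame,
                      continuous: list[str],
                      categorical: list[str],
                      group: str = "participated") -> AttritionReport:
    """Compare characteristics of follow-up participants vs nonparticipants.

    Continuous characteristics get group means, the mean difference with a
    95% CI, and a one-way ANOVA p-value; categorical ones get per-group
    proportions and a chi-square p (no continuity correction).  Chi-square
    entries with any expected cell count below 5 carry a warning.
    """
    g = df[group].astype(bool)
    a, b = df.loc[g], df.loc[~g]
    report = AttritionReport(len(a), len(b))
    for col in continuous:
        xa = pd.to_numeric(a[col], errors="coerce").dropna()
        xb = pd.to_numeric(b[col], errors="coerce").dropna()
        diff = xa.mean() - xb.mean()
        se = float(np.sqrt(xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb)))
        _, p = stats.f_oneway(xa, xb)
        report.rows.append(AttritionRow(
            col, "continuous",
            {"mean_participants": float(xa.mean()),
             "mean_nonparticipants": float(xb.mean()),
             "mean_difference": float(diff),
             "ci_low": float(diff - 1.96 * se),
             "ci_high": float(diff + 1.96 * se)},
            float(p)))
    for col in categorical:
        tab = pd.crosstab(df[col], g)
        chi2, p, _, expected = stats.chi2_contingency(tab, correction=False)
        warning = ("expected cell count < 5" if (expected < 5).any() else None)
        props = {
            "prop_participants": (tab[True] / tab[True].sum()).to_dict(),
            "prop_nonparticipants": (tab[False] / tab[False].sum()).to_dict(),
            "chi2": float(chi2),
        }
        report.rows.append(AttritionRow(col, "categorical", props, float(p), warning))
    return report
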