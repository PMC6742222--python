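"""Log-binomial risk-ratio models for quartile exposures.

The primary analysis models the risk of the offspring landing in the top
quartile of their own diet-quality score as a function of the maternal score
quartile, using a generalized linear model with binomial outcome and log
link, so exponentiated coefficients are risk ratios (RRs) with quartile 1 as
reference.  Confidence intervals are Wald on the log scale.

The log link does not guarantee fitted probabilities below 1, and with many
covariates the binomial/log fit may fail to converge; in that case the model
falls back to a Poisson working model with robust (HC1 sandwich) standard
errors — a standard epidemiological device for RR estimation — and flags
the results accordingly.

The trend test recodes the quartile factor as a single continuous term
holding the within-quartile median exposure value, and reports the two-sided
Wald p-value of that term.
"""

from __future__ import annotations

import contextlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.generalized_linear_model import DomainWarning
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning


class SeparationError(RuntimeError):
    """An exposure cell has no (or only) cases; the log-RR is unbounded."""

from .cohort import assign_quartiles, impute_covariates

__all__ = [
    "QuartileRiskModel",
    "QuartileRiskResults",
    "MODEL_A_COVARIATES",
    "MODEL_B_COVARIATES",
    "closed_form_rr",
    "quartile_rr",
    "SeparationError",
    "stratified_fit",
    "component_adjustment_scan",
    "sex_interaction_test",
    "continuous_association",
    "ContinuousAssociationResult",
]

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


@contextlib.contextmanager
def _quiet_glm():
    """Silence statsmodels' log-link domain warning and its spurious
    perfect-prediction warning on grouped saturated fits."""
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore", DomainWarning)
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        yield

#: Model A: maternal sociodemographic / lifestyle covariates.
MODEL_A_COVARIATES = (
    "maternal_age", "prepregnancy_bmi_cat", "parity", "education",
    "lactation", "physical_activity", "alcohol", "smoking",
)
#: Model B additionally adjusts for offspring sex and energy-intake quartile.
MODEL_B_COVARIATES = MODEL_A_COVARIATES + ("offspring_sex", "offspring_energy_q")

_CATEGORY_ORDER = {
    "prepregnancy_bmi_cat": ["normal", "underweight", "overweight", "obese", "missing"],
    "parity": ["0", "1", "2+"],
    "education": ["high", "medium", "skilled", "unskilled"],
    "lactation": ["<=1m", "2-6m", ">=7m"],
    "physical_activity": ["low", "high"],
    "alcohol": ["no", "yes"],
    "smoking": ["never", "occasionally", "daily"],
    "offspring_sex": ["girl", "boy"],
    "offspring_energy_q": list(QUARTILES),
}


def closed_form_rr(cases, n):
    """Unadjusted RR and Wald 95% CI from per-quartile counts.

    The reference group is the first entry.  RR_k = (x_k/n_k)/(x_1/n_1);
    SE(log RR_k) = sqrt(1/x_k - 1/n_k + 1/x_1 - 1/n_1).  This is the
    closed-form maximum-likelihood solution of the saturated one-factor
    log-binomial model and serves as the independent oracle for it.
    """
    x = np.asarray(cases, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(all="ignore"):  # empty cells legitimately yield inf/nan
        p = x / n
        rr = p / p[0]
        se = np.sqrt(1.0 / x - 1.0 / n + 1.0 / x[0] - 1.0 / n[0])
        se[0] = 0.0
        lo = rr * np.exp(-1.959963984540054 * se)
        hi = rr * np.exp(+1.959963984540054 * se)
    lo[0] = hi[0] = 1.0
    return rr, lo, hi


def quartile_rr(maternal_scores, offspring_scores):
    """Unadjusted RR(Q2..Q4 vs Q1) of top-quartile offspring score.

    Quartiles both score vectors empirically, counts offspring in their own
    top quartile within each maternal quartile, and returns the closed-form
    proportion-ratio RRs with Wald CIs as ``(rr, lo, hi, cases, n)``.
    """
    mq, _ = assign_quartiles(maternal_scores)
    oq, _ = assign_quartiles(offspring_scores)
    top = (pd.Categorical(oq).codes == 3).astype(int)
    mq = pd.Categorical(mq)
    cases = np.array([top[mq.codes == k].sum() for k in range(4)], dtype=float)
    n = np.array([(mq.codes == k).sum() for k in range(4)], dtype=float)
    rr, lo, hi = closed_form_rr(cases, n)
    return rr, lo, hi, cases, n


def _design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Dummy-coded covariate design (reference = first listed category)."""
    cols = []
    for cov in covariates:
        s = df[cov]
        order = _CATEGORY_ORDER.get(cov)
        if order is not None or s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            cats = order or sorted(s.dropna().unique().tolist())
            cats = [c for c in cats if c in set(s.astype(str))] or cats
            d = pd.get_dummies(pd.Categorical(s.astype(str), categories=cats),
                               prefix=cov, drop_first=True, dtype=float)
            d.index = df.index
            cols.append(d)
        else:
            cols.append(pd.to_numeric(s, errors="raise").rename(cov).to_frame().astype(float))
    return pd.concat(cols, axis=1) if cols else pd.DataFrame(index=df.index)


@dataclass
class QuartileRiskResults:
    """Per-quartile relative risks with Wald CIs and a trend statistic."""

    rr: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    cases: pd.Series
    n: pd.Series
    p_values: pd.Series
    trend_coef: float | None = None
    trend_p: float | None = None
    trend_scores: dict | None = None
    converged: bool = True
    fallback_used: bool = False
    model_desc: str = ""
    params: pd.Series | None = None
    bse: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cases": self.cases, "n": self.n, "RR": self.rr,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p_values,
        })

    def summary(self) -> str:
        lines = [f"Quartile risk model ({self.model_desc or 'unadjusted'})",
                 "=" * 58,
                 f"{'Q':<4}{'cases/N':>14}{'RR':>8}{'95% CI':>18}"]
        for q in self.rr.index:
            ci = f"({self.ci_low[q]:.2f}, {self.ci_high[q]:.2f})" if q != self.rr.index[0] else ""
            lines.append(f"{q:<4}{f'{int(self.cases[q])}/{int(self.n[q])}':>14}"
                         f"{self.rr[q]:>8.2f}{ci:>18}")
        if self.trend_p is not None:
            ptxt = f"{self.trend_p:.3g}" if self.trend_p >= 1e-3 else "<0.001"
            lines.append(f"p for trend: {ptxt}")
        if self.fallback_used:
            lines.append("note: Poisson/robust fallback used (log-binomial did not converge)")
        return "\n".join(lines)


class QuartileRiskModel:
    """Log-binomial model of a binary outcome on a quartile exposure.

    Parameters
    ----------
    data : DataFrame
        Individual-level rows, or grouped rows carrying ``cases``/``n``.
    exposure : str
        Column with quartile labels (Q1..Q4); Q1 is the reference.
    outcome : str
        Binary outcome column (individual-level mode).
    covariates : sequence of str, optional
        Adjustment covariates; categorical ones are dummy-coded.
    trend_scores : mapping, optional
        Quartile -> continuous coding for the trend test.  When built via
        :meth:`from_cohort` these default to the within-quartile medians of
        the exposure score.
    """

    def __init__(self, data: pd.DataFrame, exposure: str = "maternal_q",
                 outcome: str = "offspring_top_q", covariates=(),
                 trend_scores: dict | None = None, grouped: bool = False,
                 model_desc: str = ""):
        self.data = data.reset_index(drop=True)
        self.exposure = exposure
        self.outcome = outcome
        self.covariates = tuple(covariates)
        self.trend_scores = trend_scores
        self.grouped = grouped
        self.model_desc = model_desc

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_counts(cls, cases, n, labels=QUARTILES, trend_scores=None):
        """Build from per-quartile (cases, N) counts, e.g. a printed table."""
        cases = list(cases)
        n = list(n)
        if len(cases) != len(n) or len(cases) != len(labels):
            raise ValueError("cases, n and labels must have equal length")
        if any(c > t for c, t in zip(cases, n)):
            raise ValueError("cases cannot exceed n")
        df = pd.DataFrame({"q": list(labels), "cases": cases, "n": n})
        return cls(df, exposure="q", outcome=None, grouped=True,
                   trend_scores=trend_scores, model_desc="unadjusted (from counts)")

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, model: str = "unadjusted",
                    maternal_score: str = "maternal_hei",
                    offspring_score: str = "offspring_hei",
                    extra_covariates=()):
        """Build the study's primary model from a scored cohort table.

        Quartiles both scores on the analysis sample; the outcome is the
        offspring being in the top quartile of their own score.  ``model``
        selects the covariate set: ``"unadjusted"``, ``"A"`` (maternal
        covariates) or ``"B"`` (A plus offspring sex and energy quartile).
        Model covariates are imputed (median/mode/missing-category) first.
        """
        df = cohort.copy()
        mq, _ = assign_quartiles(df[maternal_score])
        oq, _ = assign_quartiles(df[offspring_score])
        df["maternal_q"] = mq
        df["offspring_top_q"] = (pd.Categorical(oq).codes == 3).astype(int)
        covs: tuple = ()
        if model == "A":
            covs = MODEL_A_COVARIATES
        elif model == "B":
            covs = MODEL_B_COVARIATES
        elif model != "unadjusted":
            raise ValueError(f"unknown model {model!r}; use 'unadjusted', 'A' or 'B'")
        if covs:
            df, _ = impute_covariates(df)
        if "offspring_energy_q" in covs:
            eq, _ = assign_quartiles(df["offspring_energy"])
            df["offspring_energy_q"] = eq
        covs = covs + tuple(extra_covariates)
        med = df.groupby("maternal_q", observed=False)[maternal_score].median()
        return cls(df, covariates=covs, trend_scores=med.to_dict(),
                   model_desc={"unadjusted": "unadjusted", "A": "model A",
                               "B": "model B"}[model]
                   + (f" + {list(extra_covariates)}" if extra_covariates else ""))

    # -- fitting ----------------------------------------------------------

    def _exog_endog(self, trend: bool = False):
        df = self.data
        if self.grouped:
            endog = np.column_stack([df["cases"], df["n"] - df["cases"]]).astype(float)
            base = df
        else:
            endog = df[self.outcome].astype(float).to_numpy()
            base = df
        q = pd.Categorical(base[self.exposure].astype(str), categories=list(QUARTILES))
        if trend:
            if self.trend_scores is None:
                raise ValueError("trend test requires trend_scores (quartile medians)")
            scores = pd.Series([self.trend_scores[c] for c in q.astype(str)],
                               index=base.index, name="trend", dtype=float)
            expo = scores.to_frame()
        else:
            expo = pd.get_dummies(q, prefix="", prefix_sep="", drop_first=True, dtype=float)
            expo.index = base.index
        X = pd.concat([expo, _design(base, self.covariates)], axis=1)
        X.insert(0, "const", 1.0)
        return endog, X

    def _start_params(self, X: pd.DataFrame) -> np.ndarray:
        # closed-form unadjusted solution as warm start: log p(ref), log RRs
        df = self.data
        start = np.zeros(X.shape[1])
        if self.grouped:
            p = (df["cases"] / df["n"]).to_numpy(float)
            labels = df[self.exposure].astype(str).to_list()
        else:
            g = df.groupby(df[self.exposure].astype(str), observed=True)[self.outcome].mean()
            labels = g.index.to_list()
            p = g.to_numpy(float)
        p = np.clip(p, 1e-10, 1 - 1e-10)
        ref = labels.index(QUARTILES[0]) if QUARTILES[0] in labels else 0
        start[0] = np.log(p[ref])
        for j, col in enumerate(X.columns):
            if col in labels:
                start[j] = np.log(p[labels.index(col)]) - start[0]
        return start

    def fit(self, with_trend: bool = True) -> QuartileRiskResults:
        cases, ns = self._counts()
        degenerate = [q for q in cases.index
                      if ns[q] > 0 and (cases[q] == 0 or cases[q] == ns[q])]
        if degenerate:
            raise SeparationError(
                f"exposure group(s) {degenerate} have no (or only) cases; "
                "the log risk ratio is unbounded")
        endog, X = self._exog_endog()
        fallback = False
        res = None
        with _quiet_glm():
            try:
                glm = sm.GLM(endog, X,
                             family=sm.families.Binomial(sm.families.links.Log()))
                res = glm.fit(start_params=self._start_params(X), maxiter=200)
                converged = bool(res.converged) and np.all(np.isfinite(res.bse))
            except Exception:
                converged = False
            if not converged:
                # Poisson working model with robust sandwich variance
                fallback = True
                if self.grouped:
                    # grouped rows: Poisson on cases with log(n) offset
                    glm = sm.GLM(self.data["cases"].astype(float), X,
                                 family=sm.families.Poisson(),
                                 offset=np.log(self.data["n"].astype(float)))
                    res = glm.fit(cov_type="HC1")
                else:
                    glm = sm.GLM(endog, X, family=sm.families.Poisson())
                    res = glm.fit(cov_type="HC1")

        params, bse = res.params, res.bse
        with _quiet_glm():
            conf = res.conf_int()
        qcols = [q for q in QUARTILES[1:] if q in X.columns]
        rr = pd.Series(1.0, index=list(QUARTILES))
        lo = pd.Series(1.0, index=list(QUARTILES))
        hi = pd.Series(1.0, index=list(QUARTILES))
        pv = pd.Series(np.nan, index=list(QUARTILES))
        for qc in qcols:
            rr[qc] = float(np.exp(params[qc]))
            lo[qc] = float(np.exp(conf.loc[qc, 0]))
            hi[qc] = float(np.exp(conf.loc[qc, 1]))
            pv[qc] = float(res.pvalues[qc])

        out = QuartileRiskResults(
            rr=rr, ci_low=lo, ci_high=hi, cases=cases, n=ns, p_values=pv,
            converged=not fallback, fallback_used=fallback,
            model_desc=self.model_desc, params=params, bse=bse)
        if with_trend and self.trend_scores is not None:
            out.trend_coef, out.trend_p = self._fit_trend(fallback)
            out.trend_scores = dict(self.trend_scores)
        return out

    def fit_trend(self) -> tuple[float, float]:
        """Median-coded trend test only: returns (coefficient, two-sided p)."""
        return self._fit_trend(False)

    def _fit_trend(self, use_fallback: bool):
        endog, X = self._exog_endog(trend=True)
        with _quiet_glm():
            try:
                if use_fallback:
                    raise RuntimeError("primary fit already fell back")
                glm = sm.GLM(endog, X,
                             family=sm.families.Binomial(sm.families.links.Log()))
                res = glm.fit(maxiter=200)
                if not res.converged or not np.all(np.isfinite(res.bse)):
                    raise RuntimeError("trend fit did not converge")
            except Exception:
                if self.grouped:
                    glm = sm.GLM(self.data["cases"].astype(float), X,
                                 family=sm.families.Poisson(),
                                 offset=np.log(self.data["n"].astype(float)))
                    res = glm.fit(cov_type="HC1")
                else:
                    glm = sm.GLM(endog, X, family=sm.families.Poisson())
                    res = glm.fit(cov_type="HC1")
            return float(res.params["trend"]), float(res.pvalues["trend"])

    def _counts(self):
        idx = list(QUARTILES)
        if self.grouped:
            c = self.data.set_index(self.exposure)["cases"].reindex(idx)
            n = self.data.set_index(self.exposure)["n"].reindex(idx)
            return c.astype(float), n.astype(float)
        g = self.data.groupby(self.data[self.exposure].astype(str), observed=True)
        c = g[self.outcome].sum().reindex(idx).astype(float)
        n = g[self.outcome].size().reindex(idx).astype(float)
        return c, n


# ---------------------------------------------------------------------------
# Secondary analyses

def stratified_fit(cohort: pd.DataFrame, stratum_var: str, model: str = "unadjusted",
                   min_stratum_size: int = 50, **kwargs):
    """Fit the quartile risk model independently within each stratum.

    Quartiles and trend codings are recomputed within each stratum's
    analysis sample.  Empty strata are skipped with a log entry; strata
    smaller than ``min_stratum_size`` are fitted but flagged.

    Returns ``(results, log)`` where results is ``[(stratum, QuartileRiskResults)]``.
    """
    results, log = [], []
    for stratum, sub in cohort.groupby(stratum_var, observed=True, sort=False):
        if len(sub) == 0:
            log.append(f"stratum {stratum!r}: empty, skipped")
            continue
        if len(sub) < min_stratum_size:
            log.append(f"stratum {stratum!r}: n={len(sub)} below minimum {min_stratum_size}")
        try:
            res = QuartileRiskModel.from_cohort(sub, model=model, **kwargs).fit()
        except (ValueError, SeparationError) as exc:
            log.append(f"stratum {stratum!r}: not fitted ({exc})")
            continue
        res.model_desc = f"{res.model_desc} | {stratum_var}={stratum}"
        results.append((stratum, res))
    return results, log


def component_adjustment_scan(cohort: pd.DataFrame, components,
                              model: str = "B",
                              prefix: str = "m_"):
    """Refit the adjusted model adding one maternal HEI component at a time.

    ``components`` are component names whose maternal per-subject scores are
    stored in columns ``prefix + name``.  Returns ``[(component,
    QuartileRiskResults)]`` in the declared order, so a component driving
    the maternal-quartile association shows as attenuation of RR(Q4).
    """
    out = []
    for comp in components:
        col = prefix + comp
        if col not in cohort.columns:
            raise KeyError(f"component column {col!r} not in cohort")
        res = QuartileRiskModel.from_cohort(cohort, model=model,
                                            extra_covariates=(col,)).fit()
        out.append((comp, res))
    return out


def sex_interaction_test(cohort: pd.DataFrame, model: str = "B") -> dict:
    """Wald test of maternal-quartile x offspring-sex interaction.

    Adds product terms of the exposure dummies with offspring sex to the
    adjusted model and jointly tests them (two-sided Wald).
    """
    m = QuartileRiskModel.from_cohort(cohort, model=model)
    endog, X = m._exog_endog()
    sex = (m.data["offspring_sex"].astype(str) == "boy").astype(float)
    names = []
    for q in QUARTILES[1:]:
        X[f"{q}:boy"] = X[q] * sex.to_numpy()
        names.append(f"{q}:boy")
    with _quiet_glm():
        try:
            glm = sm.GLM(endog, X,
                         family=sm.families.Binomial(sm.families.links.Log()))
            res = glm.fit(maxiter=200)
            if not res.converged or not np.all(np.isfinite(res.bse)):
                raise RuntimeError
            fallback = False
        except Exception:
            glm = sm.GLM(endog, X, family=sm.families.Poisson())
            res = glm.fit(cov_type="HC1")
            fallback = True
        R = np.zeros((len(names), X.shape[1]))
        for i, nm in enumerate(names):
            R[i, list(X.columns).index(nm)] = 1.0
        w = res.wald_test(R, scalar=True)
    return {"statistic": float(w.statistic), "p": float(w.pvalue),
            "df": len(names), "fallback_used": fallback}


@dataclass(frozen=True)
class ContinuousAssociationResult:
    """Offspring-score change per 10-point maternal-score increase."""

    slope_per_10: float
    ci_low: float
    ci_high: float
    r_squared: float
    n: int
    adjusted: bool

    def summary(self) -> str:
        return (f"per 10-unit maternal HEI: {self.slope_per_10:.2f} "
                f"(95% CI {self.ci_low:.2f}, {self.ci_high:.2f}) offspring HEI units; "
                f"R^2 = {self.r_squared:.1%} ({'adjusted' if self.adjusted else 'unadjusted'})")


def continuous_association(cohort: pd.DataFrame, covariates=(),
                           maternal_score: str = "maternal_hei",
                           offspring_score: str = "offspring_hei",
                           ) -> ContinuousAssociationResult:
    """Linear model of offspring score on maternal score (both continuous).

    The slope is rescaled to a per-10-point maternal increase; the model's
    coefficient of determination is reported.  Adding ``covariates`` yields
    the adjusted slope/variance-explained variants.
    """
    df = cohort.copy()
    if covariates:
        df, _ = impute_covariates(df)
        if "offspring_energy_q" in covariates:
            eq, _ = assign_quartiles(df["offspring_energy"])
            df["offspring_energy_q"] = eq
    y = pd.to_numeric(df[offspring_score], errors="raise").astype(float)
    X = pd.concat([df[maternal_score].astype(float).rename("maternal"),
                   _design(df, covariates)], axis=1)
    X.insert(0, "const", 1.0)
    if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    res = sm.OLS(y, X.astype(float)).fit()
    conf = res.conf_int().loc["maternal"]
    return ContinuousAssociationResult(
        slope_per_10=float(res.params["maternal"] * 10),
        ci_low=float(conf[0] * 10), ci_high=float(conf[1] * 10),
        r_squared=float(res.rsquared), n=int(res.nobs),
        adjusted=bool(covariates))
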