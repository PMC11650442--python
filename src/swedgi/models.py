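"""Association, interaction and joint-effect models.

The model battery links diet-quality categories, microbial alpha-diversity
and the metabolic syndrome:

* linear (OLS) models of a continuous outcome (the Shannon index) across
  exposure categories, with the trend coefficient taken from the ordered
  category index entered as a single continuous covariate;
* logistic models (GLM, binomial family, IRLS) of MetS, reporting per-
  category odds ratios against the lowest category plus the same trend test;
* mutual adjustment of the 12 index components (each modelled with the
  other 11 entered simultaneously, coded continuously 0-4);
* multiplicative interaction tests (Wald test on a product term of the two
  continuously coded factors);
* joint-effect cross-classification: both exposures binned (tertiles by
  default), one logistic model with 8 indicator terms against the
  (low, low) reference cell.

Covariates come in nested tiers: the basic tier adjusts for age, sex, study
site and total energy intake; the main tier adds smoking, leisure-time
physical activity and education; further tiers add BMI, fibre intake, the
Shannon index or the diet-index category.  Categorical covariates enter as
indicator terms; all fits are complete-case; all p-values are two-sided
Wald tests, with 95 % confidence intervals of estimate +/- 1.96 SE on the
link scale (exponentiated for odds ratios).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diversity import quantile_groups

__all__ = [
    "TIERS",
    "CATEGORICAL_COVARIATES",
    "ModelSpec",
    "ModelResult",
    "fit_linear_trend",
    "fit_logistic",
    "fit_mutually_adjusted_components",
    "test_interaction",
    "joint_effect",
    "significance_label",
]

Z95 = 1.959963984540054

#: covariates entered as indicator terms (reference = first sorted level)
CATEGORICAL_COVARIATES = {"sex", "site", "smoking", "physical_activity", "education"}

_BASIC = ("age", "sex", "site", "energy")
_MAIN = _BASIC + ("smoking", "physical_activity", "education")
TIERS: dict[str, tuple[str, ...]] = {
    "none": (),
    "basic": _BASIC,
    "main": _MAIN,
    "main+BMI": _MAIN + ("bmi",),
    "main+fibre": _MAIN + ("fibre",),
    "main+shannon": _MAIN + ("shannon",),
    "main+swedgi": _MAIN + ("swedgi_category",),
}


@dataclass
class ModelSpec:
    """Declarative description of one model fit."""

    outcome: str
    exposure: str
    exposure_coding: str = "category_as_continuous"  # or "per_category_indicator"
    covariate_tier: str = "main"
    interaction_terms: list = dc_field(default_factory=list)
    extra_covariates: list = dc_field(default_factory=list)

    def covariates(self) -> list[str]:
        if self.covariate_tier not in TIERS:
            raise ValueError(
                f"unknown covariate tier {self.covariate_tier!r}; known: {sorted(TIERS)}"
            )
        covs = list(TIERS[self.covariate_tier]) + list(self.extra_covariates)
        # never adjust an exposure for itself
        return [c for c in covs if c != self.exposure and c != self.outcome]


@dataclass
class ModelResult:
    """One fitted effect: beta or OR with Wald inference."""

    term: str
    estimate: float
    se: float
    ci95: tuple[float, float]
    p: float
    p_trend: float
    n_used: int
    scale: str  # "beta" or "or"
    model_spec: Optional[ModelSpec] = None
    extras: dict = dc_field(default_factory=dict)


def significance_label(p: float) -> str:
    """Reporting convention: significant below 0.05, tendency 0.05-0.10."""
    if p < 0.05:
        return "significant"
    if p <= 0.10:
        return "tendency"
    return "ns"


# ---------------------------------------------------------------- design --

def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns: those not increasing the rank incrementally
        bad = []
        r = 0
        for j in range(arr.shape[1]):
            rj = np.linalg.matrix_rank(arr[:, : j + 1])
            if rj == r:
                bad.append(X.columns[j])
            r = rj
        raise ValueError(f"design matrix is rank deficient; collinear fields: {bad}")


def _design(data: pd.DataFrame, fields: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for f in fields:
        if f not in data.columns:
            raise ValueError(f"model field {f!r} missing from data")
        if f in CATEGORICAL_COVARIATES:
            s = data[f].astype("category")
            dummies = pd.get_dummies(s, prefix=f, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c]
        else:
            cols[f] = data[f].astype(float)
    X = pd.DataFrame(cols, index=data.index)
    X.insert(0, "const", 1.0)
    return X


def _complete_cases(data: pd.DataFrame, fields: Sequence[str]) -> pd.DataFrame:
    missing_cols = [f for f in fields if f not in data.columns]
    if missing_cols:
        raise ValueError(f"model field(s) missing from data: {missing_cols}")
    return data.dropna(subset=list(fields)).reset_index(drop=True)


def _fit_ols(y: pd.Series, X: pd.DataFrame):
    _check_rank(X)
    return sm.OLS(y.astype(float), X.astype(float)).fit()


def _fit_glm_binomial(y: pd.Series, X: pd.DataFrame):
    _check_rank(X)
    model = sm.GLM(y.astype(float), X.astype(float), family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise RuntimeError("logistic model did not converge within 100 IRLS iterations")
    if np.any(np.abs(res.params) > 30):
        big = [c for c, v in res.params.items() if abs(v) > 30]
        raise RuntimeError(
            f"(quasi-)complete separation suspected: extreme coefficients for {big}"
        )
    return res


# ----------------------------------------------------------------- fits --

def fit_linear_trend(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """OLS of a continuous outcome with the exposure category as a trend.

    The trend beta and p come from the category index entered continuously;
    per-category least-squares (covariate-adjusted) means are also emitted
    in ``extras["adjusted_means"]``.
    """
    covs = spec.covariates()
    fields = [spec.outcome, spec.exposure, *covs]
    df = _complete_cases(data, fields)
    X = _design(df, [spec.exposure, *covs])
    res = _fit_ols(df[spec.outcome], X)
    beta = float(res.params[spec.exposure])
    se = float(res.bse[spec.exposure])
    p = float(res.pvalues[spec.exposure])

    # per-category adjusted means: indicator fit, predicted at covariate means
    cats = np.sort(df[spec.exposure].unique())
    means: dict = {}
    if 2 <= len(cats) <= 12:
        dummies = pd.get_dummies(df[spec.exposure], prefix="cat", dtype=float).iloc[:, 1:]
        Xi = pd.concat([_design(df, covs), dummies], axis=1)
        res_i = _fit_ols(df[spec.outcome], Xi)
        base = {c: float(Xi[c].mean()) for c in Xi.columns if not c.startswith("cat_")}
        for c in cats:
            row = dict(base)
            for dcol in dummies.columns:
                row[dcol] = 1.0 if dcol == f"cat_{c}" else 0.0
            means[c] = float(sum(res_i.params[k] * v for k, v in row.items()))
    return ModelResult(
        term=spec.exposure,
        estimate=beta,
        se=se,
        ci95=(beta - Z95 * se, beta + Z95 * se),
        p=p,
        p_trend=p,
        n_used=len(df),
        scale="beta",
        model_spec=spec,
        extras={"adjusted_means": means},
    )


def fit_logistic(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Logistic model of a binary outcome: per-category ORs plus trend.

    Returns the trend effect (OR per one category) as the headline estimate;
    ``extras["per_category"]`` maps each non-reference category to
    ``(OR, ci_low, ci_high)`` versus the lowest category.
    """
    covs = spec.covariates()
    fields = [spec.outcome, spec.exposure, *covs]
    df = _complete_cases(data, fields)
    y = df[spec.outcome].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {spec.outcome!r} must be binary 0/1")

    X = _design(df, [spec.exposure, *covs])
    res = _fit_glm_binomial(y, X)
    beta = float(res.params[spec.exposure])
    se = float(res.bse[spec.exposure])
    p = float(res.pvalues[spec.exposure])

    per_category: dict = {}
    cats = np.sort(df[spec.exposure].unique())
    if 2 <= len(cats) <= 12:
        dummies = pd.get_dummies(df[spec.exposure], prefix="cat", dtype=float).iloc[:, 1:]
        Xi = pd.concat([_design(df, covs), dummies], axis=1)
        res_i = _fit_glm_binomial(y, Xi)
        for c in cats[1:]:
            b = float(res_i.params[f"cat_{c}"])
            s = float(res_i.bse[f"cat_{c}"])
            per_category[c] = (np.exp(b), np.exp(b - Z95 * s), np.exp(b + Z95 * s))
    return ModelResult(
        term=spec.exposure,
        estimate=float(np.exp(beta)),
        se=se,
        ci95=(float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))),
        p=p,
        p_trend=p,
        n_used=len(df),
        scale="or",
        model_spec=spec,
        extras={"per_category": per_category, "log_or": beta},
    )


def fit_mutually_adjusted_components(
    data: pd.DataFrame,
    component_cols: Sequence[str],
    outcome: str,
    covariate_tier: str = "main",
) -> dict[str, ModelResult]:
    """One model per index component, adjusted for the other components.

    Each component enters continuously (0-4); the model for component *j*
    includes the remaining components simultaneously, on top of the tier
    covariates.  Binary outcomes get logistic fits, continuous ones OLS.
    """
    component_cols = list(component_cols)
    results: dict[str, ModelResult] = {}
    binary = set(pd.Series(data[outcome].dropna().unique())) <= {0, 1, 0.0, 1.0, True, False}
    for comp in component_cols:
        others = [c for c in component_cols if c != comp]
        spec = ModelSpec(
            outcome=outcome,
            exposure=comp,
            covariate_tier=covariate_tier,
            extra_covariates=others,
        )
        results[comp] = fit_logistic(data, spec) if binary else fit_linear_trend(data, spec)
    return results


def test_interaction(data: pd.DataFrame, spec: ModelSpec, a: str, b: str) -> float:
    """Wald p-value for the product term a x b added to the main-effects model.

    Both factors are treated as continuous (e.g. Shannon x diet-index
    category).  The outcome determines the family (binary -> logistic).
    """
    if a == b:
        raise ValueError("interaction of a variable with itself is not identified")
    covs = [c for c in spec.covariates() if c not in (a, b)]
    fields = [spec.outcome, a, b, *covs]
    df = _complete_cases(data, fields)
    X = _design(df, covs)
    X[a] = df[a].astype(float)
    X[b] = df[b].astype(float)
    X[f"{a}:{b}"] = df[a].astype(float) * df[b].astype(float)
    y = df[spec.outcome]
    binary = set(np.unique(y.astype(float))) <= {0.0, 1.0}
    res = _fit_glm_binomial(y.astype(float), X) if binary else _fit_ols(y, X)
    return float(res.pvalues[f"{a}:{b}"])


def joint_effect(
    data: pd.DataFrame,
    exposure_a: str,
    exposure_b: str,
    covariate_tier: str = "main",
    q: int = 3,
    already_binned: bool = False,
) -> dict:
    """Cross-classified ORs for two exposures versus the (low, low) cell.

    Both exposures are binned into ``q`` quantile groups (tertiles by
    default) unless ``already_binned``; a single logistic model with
    ``q*q - 1`` indicator terms plus the tier covariates yields an OR for
    every non-reference cell.  Returns a dict with ``or_grid``, ``ci_low``,
    ``ci_high`` and ``n`` DataFrames (rows = exposure-a group, columns =
    exposure-b group) and the raw fit under ``result``.
    """
    spec = ModelSpec(outcome="mets", exposure=exposure_a, covariate_tier=covariate_tier)
    covs = [c for c in spec.covariates() if c not in (exposure_a, exposure_b)]
    fields = ["mets", exposure_a, exposure_b, *covs]
    df = _complete_cases(data, fields)
    ga = df[exposure_a].astype(int) if already_binned else quantile_groups(df[exposure_a], q)
    gb = df[exposure_b].astype(int) if already_binned else quantile_groups(df[exposure_b], q)

    counts = pd.crosstab(ga, gb)
    for i in range(1, q + 1):
        for j in range(1, q + 1):
            if counts.reindex(index=[i], columns=[j]).fillna(0).iat[0, 0] == 0:
                raise ValueError(f"empty joint-effect cell (a={i}, b={j})")

    X = _design(df, covs)
    cell_cols = []
    for i in range(1, q + 1):
        for j in range(1, q + 1):
            if (i, j) == (1, 1):
                continue
            col = f"cell_{i}_{j}"
            X[col] = ((ga == i) & (gb == j)).astype(float).to_numpy()
            cell_cols.append((i, j, col))
    res = _fit_glm_binomial(df["mets"].astype(float), X)

    grid = pd.DataFrame(1.0, index=range(1, q + 1), columns=range(1, q + 1))
    lo = grid.copy()
    hi = grid.copy()
    for i, j, col in cell_cols:
        b = float(res.params[col])
        s = float(res.bse[col])
        grid.loc[i, j] = np.exp(b)
        lo.loc[i, j] = np.exp(b - Z95 * s)
        hi.loc[i, j] = np.exp(b + Z95 * s)
    return {
        "or_grid": grid,
        "ci_low": lo,
        "ci_high": hi,
        "n": counts.reindex(index=range(1, q + 1), columns=range(1, q + 1)),
        "n_used": len(df),
        "result": res,
    }
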