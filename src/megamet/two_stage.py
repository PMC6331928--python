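"""Two-stage meta-analysis: per-cohort regression, effect sizes, pooling.

Stage one fits, within each cohort separately, an ordinary least-squares
regression of the outcome on an intercept, the diagnosis indicator and the
covariates, and converts the diagnosis t-statistic to Cohen's d,

    d = t * (n1 + n2) / (sqrt(n1 * n2) * sqrt(df)),

with the large-sample variance

    v = (n1 + n2) / (n1 * n2) + d^2 / (2 * (n1 + n2 - 2)).

Stage two pools the cohort effect sizes with inverse-variance weights
w_i = 1 / (v_i + tau^2), where the between-study variance tau^2 is the
restricted-maximum-likelihood (REML) estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import AnalysisSubset, CovariateSpec, FitResult


class EstimationError(RuntimeError):
    """A per-cohort regression could not be estimated."""


@dataclass(frozen=True)
class OLSFit:
    beta_dx: float
    se_beta: float
    t: float
    df: int
    sigma2: float  # residual variance (unbiased)


@dataclass(frozen=True)
class CohortSummary:
    """Aggregated stage-one summary for one cohort."""

    cohort_id: str
    d: float
    v: float
    n1: int
    n2: int
    t: float
    df: int

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError("variance of d must be positive")
        if self.df < 1 or self.n1 < 1 or self.n2 < 1:
            raise ValueError("degenerate cohort summary")


@dataclass(frozen=True)
class RandomEffectsPool:
    """Inverse-variance random-effects pooled estimate."""

    mu_hat: float
    se_mu: float
    tau2: float
    weights: tuple[float, ...]
    k: int
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if not (np.isfinite(w).all() and (w > 0).all()):
            raise ValueError("weights must be positive and finite")


def build_design(
    df: pd.DataFrame, roi: str, spec: CovariateSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix [1, dx, covariates...] and outcome vector."""
    names = ["intercept", "dx", *spec.covariates]
    X = np.column_stack(
        [np.ones(len(df)), df["dx"].to_numpy(float)]
        + [df[c].to_numpy(float) for c in spec.covariates]
    )
    y = df[roi].to_numpy(float)
    return X, y, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the first column collinear with its predecessors
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise EstimationError(
                    f"design is rank deficient: column {names[j]!r} is collinear"
                )
        raise EstimationError("design is rank deficient")


def fit_cohort_ols(df: pd.DataFrame, roi: str, spec: CovariateSpec) -> OLSFit:
    """OLS of the outcome on intercept + diagnosis + covariates in one cohort.

    Returns the raw diagnosis coefficient, its t-statistic and the residual
    degrees of freedom df = n - p.
    """
    import statsmodels.api as sm

    groups = set(df["dx"].unique())
    if groups != {0, 1}:
        raise EstimationError("both diagnostic groups must be present")
    X, y, names = build_design(df, roi, spec)
    if len(y) <= X.shape[1]:
        raise EstimationError("fewer observations than parameters")
    _check_rank(X, names)
    res = sm.OLS(y, X).fit()
    sigma2 = float(res.mse_resid)
    if sigma2 <= 0 or not np.isfinite(sigma2):
        raise EstimationError("zero residual variance: degenerate fit")
    return OLSFit(
        beta_dx=float(res.params[1]),
        se_beta=float(res.bse[1]),
        t=float(res.tvalues[1]),
        df=int(res.df_resid),
        sigma2=sigma2,
    )


def t_to_d(t: float, n1: int, n2: int, df: float) -> float:
    """Cohen's d from a regression t-statistic.

    For the plain two-group comparison (no covariates, df = n1 + n2 - 2)
    this equals the direct standardized mean difference rescaled by
    sqrt((n1 + n2) / df).
    """
    if df <= 0:
        raise ValueError("df must be positive")
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    return t * (n1 + n2) / (math.sqrt(n1 * n2) * math.sqrt(df))


def d_conversion_factor(n1: int, n2: int, df: float) -> float:
    """Multiplier c with d = c * t; also the model-based SE of d."""
    return (n1 + n2) / (math.sqrt(n1 * n2) * math.sqrt(df))


def var_of_d(d: float, n1: int, n2: int) -> float:
    """Large-sample variance of Cohen's d for group sizes n1, n2."""
    n = n1 + n2
    if n1 < 2 or n2 < 2 or n <= 2:
        raise ValueError("need at least two subjects per group")
    return n / (n1 * n2) + d * d / (2 * (n - 2))


def cohort_summaries(subset: AnalysisSubset) -> list[CohortSummary]:
    """Stage one: per-cohort OLS and effect-size conversion.

    Only two-stage-eligible cohorts are summarized.
    """
    out = []
    for cohort in subset.two_stage_eligible:
        rows = subset.df[subset.df["cohort"] == cohort]
        fit = fit_cohort_ols(rows, subset.roi, subset.spec)
        n1 = int((rows["dx"] == 1).sum())
        n2 = int((rows["dx"] == 0).sum())
        d = t_to_d(fit.t, n1, n2, fit.df)
        out.append(
            CohortSummary(
                cohort_id=cohort,
                d=d,
                v=var_of_d(d, n1, n2),
                n1=n1,
                n2=n2,
                t=fit.t,
                df=fit.df,
            )
        )
    return out


# ---------------------------------------------------------------------------
# REML between-study variance and pooling
# ---------------------------------------------------------------------------


def restricted_loglik(tau2: float, d: np.ndarray, v: np.ndarray) -> float:
    """Restricted log-likelihood of the random-effects model at tau^2.

    l_R(tau^2) = -1/2 [ sum ln(v_i + tau^2) + ln sum 1/(v_i + tau^2)
                        + sum (d_i - mu_hat)^2 / (v_i + tau^2) ]
    with mu_hat the inverse-variance weighted mean at that tau^2.
    """
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * d) / np.sum(w))
    return -0.5 * float(
        np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (d - mu) ** 2)
    )


def reml_tau2(
    summaries: Sequence[CohortSummary],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[float, bool]:
    """REML estimate of the between-study variance tau^2 (truncated at 0).

    Uses the standard Fisher-scoring fixed-point iteration; if it fails to
    settle within ``max_iter`` the bounded maximizer of the restricted
    log-likelihood is taken instead and the flag set to False.  A single
    study yields tau^2 = 0 (no between-study information).
    """
    if len(summaries) < 2:
        return 0.0, False
    d = np.array([s.d for s in summaries], float)
    v = np.array([s.v for s in summaries], float)
    if not (np.isfinite(d).all() and np.isfinite(v).all() and (v > 0).all()):
        raise ValueError("non-finite or non-positive summary inputs")

    tau2 = max(0.0, float(np.var(d, ddof=1) - np.mean(v)))
    converged = False
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * d) / np.sum(w)
        num = np.sum(w**2 * ((d - mu) ** 2 - v)) + np.sum(w**2) / np.sum(w)
        new = max(0.0, float(num / np.sum(w**2)))
        if abs(new - tau2) < tol:
            tau2 = new
            converged = True
            break
        tau2 = new
    if not converged:
        hi = max(1.0, 10.0 * float(np.var(d, ddof=1) + np.max(v)))
        res = optimize.minimize_scalar(
            lambda t2: -restricted_loglik(t2, d, v),
            bounds=(0.0, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        tau2 = max(0.0, float(res.x))
        if restricted_loglik(0.0, d, v) >= restricted_loglik(tau2, d, v):
            tau2 = 0.0
    return tau2, converged


def pool_random_effects(
    summaries: Sequence[CohortSummary], tau2: float | None = None
) -> RandomEffectsPool:
    """Inverse-variance weighted random-effects pooling.

    w_i = 1/(v_i + tau^2); the pooled mean is the weighted average of the
    cohort d_i, SE = (sum w_i)^(-1/2), CI the Wald 95% interval.
    """
    if not summaries:
        raise ValueError("need at least one cohort summary")
    if tau2 is None:
        tau2, _ = reml_tau2(summaries)
    d = np.array([s.d for s in summaries], float)
    v = np.array([s.v for s in summaries], float)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * d) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return RandomEffectsPool(
        mu_hat=mu,
        se_mu=se,
        tau2=tau2,
        weights=tuple(w),
        k=len(summaries),
        ci95=(mu - 1.96 * se, mu + 1.96 * se),
    )


def meta_fitresult(pool: RandomEffectsPool, n1: int, n2: int) -> FitResult:
    """Package a pooled estimate as a :class:`FitResult` (method ``meta_re``).

    No log-likelihood or BIC is reported: the study-level restricted
    likelihood is not comparable with the subject-level model fits.
    """
    z = pool.mu_hat / pool.se_mu
    p = 2 * stats.norm.sf(abs(z))
    return FitResult(
        method="meta_re",
        d=pool.mu_hat,
        se_d=pool.se_mu,
        ci95=pool.ci95,
        t=z,
        df=float(pool.k - 1),
        p=float(p),
        tau2=pool.tau2,
        converged=True,
        n1=n1,
        n2=n2,
    )


def run_meta(subset: AnalysisSubset) -> tuple[FitResult, list[CohortSummary]]:
    """Full two-stage pipeline on an analysis-ready subset."""
    from .data_model import NoEstimableCohortsError

    if not subset.two_stage_eligible:
        raise NoEstimableCohortsError(
            f"no estimable cohorts for two-stage analysis of {subset.roi!r}"
        )
    summaries = cohort_summaries(subset)
    pool = pool_random_effects(summaries)
    n1 = sum(s.n1 for s in summaries)
    n2 = sum(s.n2 for s in summaries)
    return meta_fitresult(pool, n1, n2), summaries
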