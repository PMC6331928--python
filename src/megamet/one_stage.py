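"""One-stage mega-analysis: pooled regression and mixed-effects models.

All subjects are analyzed in a single model.  Clustering within cohorts is
handled either by cohort dummy variables (multiple linear regression) or by
a Gaussian random intercept per cohort (linear mixed-effects model fitted
by restricted maximum likelihood), optionally extended with a random slope
for the diagnosis effect.  Cohen's d is obtained from the diagnosis
t-statistic with the same conversion used in the two-stage arm, and model
fit is compared with the Bayesian information criterion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AnalysisSubset, CovariateSpec, FitResult
from .two_stage import EstimationError, _check_rank, d_conversion_factor, t_to_d

RANDOM_INTERCEPT = "intercept"
RANDOM_INTERCEPT_SLOPE = "intercept_slope"


@dataclass(frozen=True)
class MixedModelSpec:
    """Random-effects structure of the mixed model.

    ``intercept`` fits a cohort random intercept (one variance parameter);
    ``intercept_slope`` additionally lets the diagnosis effect vary by
    cohort (intercept + slope with unstructured 2x2 covariance).  The slope
    spec always includes the intercept.
    """

    random: str = RANDOM_INTERCEPT
    reml: bool = True

    def __post_init__(self) -> None:
        if self.random not in (RANDOM_INTERCEPT, RANDOM_INTERCEPT_SLOPE):
            raise ValueError(f"unknown random structure {self.random!r}")

    @property
    def n_varcomps(self) -> int:
        # intercept var | intercept var + slope var + covariance
        return 1 if self.random == RANDOM_INTERCEPT else 3


@dataclass
class MixedModelFit:
    """Fitted mixed model: fixed effects, variance components, likelihoods."""

    spec: MixedModelSpec
    beta: dict[str, float] = field(default_factory=dict)
    se_beta: dict[str, float] = field(default_factory=dict)
    sigma_u2: float | None = None
    sigma_b2: float | None = None
    sigma_ub: float | None = None
    sigma_e2: float | None = None
    loglik_reml: float | None = None
    loglik_ml: float | None = None
    n_obs: int = 0
    n_fixed: int = 0
    converged: bool = False
    note: str = ""


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion, -2*loglik + k*ln(n); lower is better."""
    if n < 1 or k < 1:
        raise ValueError("need n >= 1 and k >= 1")
    return -2.0 * loglik + k * math.log(n)


def _mega_design(
    subset: AnalysisSubset,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pooled design: intercept + dx + covariates + (K-1) cohort dummies.

    The reference level is the first cohort by sorted label; the estimate
    of the diagnosis effect is invariant to this choice.
    """
    df, spec = subset.df, subset.spec
    cohorts = sorted(df["cohort"].unique())
    names = ["intercept", "dx", *spec.covariates]
    cols = [np.ones(len(df)), df["dx"].to_numpy(float)]
    cols += [df[c].to_numpy(float) for c in spec.covariates]
    for c in cohorts[1:]:
        cols.append((df["cohort"] == c).to_numpy(float))
        names.append(f"cohort[{c}]")
    return np.column_stack(cols), df[subset.roi].to_numpy(float), names


def fit_mega_lr(subset: AnalysisSubset) -> FitResult:
    """Pooled OLS with cohort dummy variables (method ``mega_lr``).

    d is converted from the diagnosis t-statistic with n1, n2 the total
    patient/control counts and df = n - p; BIC uses the Gaussian maximum
    likelihood with k = p + 1 parameters (coefficients + residual variance).
    """
    import statsmodels.api as sm

    X, y, names = _mega_design(subset)
    n, p = X.shape
    if len(subset.df["cohort"].unique()) < 2:
        warnings.warn("single cohort: dummies degenerate to plain OLS")
    try:
        _check_rank(X, names)
    except EstimationError as e:
        raise EstimationError(str(e)) from None
    res = sm.OLS(y, X).fit()
    n1, n2 = subset.n1, subset.n2
    t = float(res.tvalues[1])
    df_resid = float(res.df_resid)
    d = t_to_d(t, n1, n2, df_resid)
    se_d = d_conversion_factor(n1, n2, df_resid)
    llf = float(res.llf)  # Gaussian ML log-likelihood
    return FitResult(
        method="mega_lr",
        d=d,
        se_d=se_d,
        ci95=(d - 1.96 * se_d, d + 1.96 * se_d),
        beta_dx=float(res.params[1]),
        t=t,
        df=df_resid,
        p=float(res.pvalues[1]),
        loglik=llf,
        bic=bic(llf, p + 1, n),
        converged=True,
        n_obs=n,
        n1=n1,
        n2=n2,
    )


def _profile_ri_loglik(
    lam: float,
    X: np.ndarray,
    y: np.ndarray,
    group_stats: list[tuple[int, np.ndarray, float]],
    reml: bool,
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profiled log-likelihood of the random-intercept model at lam = s_u^2/s_e^2.

    With V = s_e^2 (I + lam Z Z'), both the GLS coefficients and s_e^2 have
    closed forms given lam; the group structure enters only through
    per-cohort sums, so evaluation is O(n p^2).  Returns (loglik, beta,
    cov_beta_unscaled, sigma_e2); multiply cov by sigma_e2 for SEs.
    """
    n, p = X.shape
    A = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    logdet = 0.0
    for ni, xs, ys in group_stats:
        c = lam / (1.0 + lam * ni)
        A = A - c * np.outer(xs, xs)
        Xty = Xty - c * xs * ys
        yty -= c * ys * ys
        logdet += math.log1p(lam * ni)
    beta = np.linalg.solve(A, Xty)
    q = max(yty - float(beta @ Xty), 1e-300)
    dof = n - p if reml else n
    sigma_e2 = q / dof
    ll = -0.5 * (dof * math.log(sigma_e2) + logdet + q / sigma_e2)
    ll -= 0.5 * dof * math.log(2 * math.pi)
    if reml:
        ll -= 0.5 * float(np.linalg.slogdet(A)[1])
    return ll, beta, np.linalg.inv(A), sigma_e2


def _fit_ri(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    reml: bool = True,
) -> tuple[float, np.ndarray, np.ndarray, float, float]:
    """Random-intercept fit by 1-D bounded search over the variance ratio.

    The variance ratio is profiled out exactly, so the search is a scalar
    maximization on [0, inf) — robust even when the optimum sits on the
    sigma_u^2 = 0 boundary.  Returns (loglik, beta, cov_beta, sigma_u2,
    sigma_e2).
    """
    from scipy import optimize

    group_stats = []
    for g in np.unique(groups):
        idx = groups == g
        group_stats.append(
            (int(idx.sum()), X[idx].sum(axis=0), float(y[idx].sum()))
        )

    def neg(lam: float) -> float:
        return -_profile_ri_loglik(lam, X, y, group_stats, reml)[0]

    hi = 1e4
    while True:
        res = optimize.minimize_scalar(
            neg, bounds=(0.0, hi), method="bounded", options={"xatol": 1e-12}
        )
        if res.x < 0.99 * hi or hi >= 1e10:
            break
        hi *= 100.0
    lam = float(res.x)
    if neg(0.0) <= res.fun:  # boundary check: no between-cohort variance
        lam = 0.0
    ll, beta, cov_unscaled, sigma_e2 = _profile_ri_loglik(
        lam, X, y, group_stats, reml
    )
    return ll, beta, cov_unscaled * sigma_e2, lam * sigma_e2, sigma_e2


def fit_lmm(
    subset: AnalysisSubset,
    mm: MixedModelSpec | None = None,
    with_ml: bool = False,
    maxiter: int = 500,
) -> MixedModelFit:
    """Linear mixed model by REML (random intercept, optional random slope).

    The random-intercept model is fitted by an exact profiled scalar
    search over the variance ratio (stable at the zero-variance boundary).
    The random-slope extension is fitted with statsmodels' MixedLM; its
    non-convergence (iteration cap, non-finite objective or standard
    errors) is a result state: the fit is returned with ``converged=False``
    and estimates absent, never raised.  ``with_ml`` additionally maximizes
    the full likelihood at its own optimum.
    """
    mm = mm or MixedModelSpec()
    df, spec = subset.df, subset.spec
    if df["cohort"].nunique() < 2:
        raise EstimationError("mixed model needs >= 2 cohorts")
    fixed_names = ["intercept", "dx", *spec.covariates]
    X = np.column_stack(
        [np.ones(len(df)), df["dx"].to_numpy(float)]
        + [df[c].to_numpy(float) for c in spec.covariates]
    )
    y = df[subset.roi].to_numpy(float)
    groups = df["cohort"].to_numpy()
    fit = MixedModelFit(spec=mm, n_obs=len(df), n_fixed=len(fixed_names))

    if mm.random == RANDOM_INTERCEPT:
        try:
            ll, beta, cov_beta, su2, se2 = _fit_ri(X, y, groups, reml=True)
        except (np.linalg.LinAlgError, ValueError, OverflowError) as e:
            fit.note = f"REML optimization failed: {e}"
            return fit
        fit.beta = dict(zip(fixed_names, beta))
        fit.se_beta = dict(zip(fixed_names, np.sqrt(np.diag(cov_beta))))
        fit.sigma_u2, fit.sigma_e2 = su2, se2
        fit.loglik_reml = ll
        fit.converged = True
        if with_ml:
            fit.loglik_ml = _fit_ri(X, y, groups, reml=False)[0]
        return fit

    return _fit_ris_statsmodels(fit, X, y, groups, fixed_names, df, with_ml, maxiter)


def _fit_ris_statsmodels(
    fit: MixedModelFit,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    fixed_names: list[str],
    df: pd.DataFrame,
    with_ml: bool,
    maxiter: int,
) -> MixedModelFit:
    """Random-intercept + random-slope fit via statsmodels MixedLM."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    exog = pd.DataFrame(X, columns=fixed_names, index=df.index)
    exog_re = exog[["intercept", "dx"]]

    def _try_fit(reml: bool):
        model = sm.MixedLM(y, exog, groups=groups, exog_re=exog_re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            res = model.fit(reml=reml, maxiter=maxiter)
        ok = (
            bool(res.converged)
            and np.isfinite(res.fe_params.to_numpy()).all()
            and np.isfinite(res.bse_fe.to_numpy()).all()
            and np.isfinite(res.llf)
        )
        return res, ok

    try:
        res, ok = _try_fit(reml=True)
    except (np.linalg.LinAlgError, ValueError, OverflowError) as e:
        fit.note = f"REML optimization failed: {e}"
        return fit
    if not ok:
        fit.note = "REML iteration did not converge"
        return fit

    fit.beta = dict(zip(fixed_names, res.fe_params.to_numpy(float)))
    fit.se_beta = dict(zip(fixed_names, res.bse_fe.to_numpy(float)))
    cov_re = np.atleast_2d(np.asarray(res.cov_re, float))
    fit.sigma_u2 = float(cov_re[0, 0])
    fit.sigma_b2 = float(cov_re[1, 1])
    fit.sigma_ub = float(cov_re[0, 1])
    fit.sigma_e2 = float(res.scale)
    fit.loglik_reml = float(res.llf)
    fit.converged = True

    if with_ml:
        try:
            res_ml, ok_ml = _try_fit(reml=False)
            if ok_ml:
                fit.loglik_ml = float(res_ml.llf)
            else:
                fit.note = (fit.note + "; " if fit.note else "") + "ML refit did not converge"
        except (np.linalg.LinAlgError, ValueError, OverflowError):
            fit.note = (fit.note + "; " if fit.note else "") + "ML refit failed"
    return fit


def lmm_to_fitresult(fit: MixedModelFit, n1: int, n2: int) -> FitResult:
    """Convert a mixed-model diagnosis effect to a :class:`FitResult`.

    t = beta_dx / se; df = n_obs - n_fixed; d via the same t-to-d
    conversion as elsewhere, with SE(d) the conversion factor itself.  BIC
    counts fixed effects + variance components + the residual variance,
    evaluated at the restricted log-likelihood.
    """
    method = (
        "mega_lmm_ri" if fit.spec.random == RANDOM_INTERCEPT else "mega_lmm_ris"
    )
    if not fit.converged:
        return FitResult(method=method, converged=False, note=fit.note)
    beta = fit.beta["dx"]
    se = fit.se_beta["dx"]
    t = beta / se
    df = float(fit.n_obs - fit.n_fixed)
    d = t_to_d(t, n1, n2, df)
    se_d = d_conversion_factor(n1, n2, df)
    k = fit.n_fixed + fit.spec.n_varcomps + 1
    p = 2 * stats.norm.sf(abs(t))
    return FitResult(
        method=method,
        d=d,
        se_d=se_d,
        ci95=(d - 1.96 * se_d, d + 1.96 * se_d),
        beta_dx=beta,
        t=t,
        df=df,
        p=float(p),
        loglik=fit.loglik_reml,
        bic=bic(fit.loglik_reml, k, fit.n_obs),
        converged=True,
        n_obs=fit.n_obs,
        n1=n1,
        n2=n2,
        note=fit.note,
    )


def lrt_random_slope(
    fit_ri: MixedModelFit, fit_ris: MixedModelFit, alpha: float = 0.05
) -> tuple[float, float, str, str]:
    """Likelihood-ratio test of random slope vs random intercept only.

    Both fits share the same fixed effects, so the REML log-likelihoods are
    comparable.  Because the slope variance is tested on the boundary of
    its parameter space, the null distribution is the 50:50 mixture of
    chi-square(1) and chi-square(2).  Returns (statistic, p, preferred
    model, reason); a non-converged slope model falls back to the
    random-intercept model.
    """
    if not fit_ri.converged:
        raise EstimationError("random-intercept model did not converge")
    if not fit_ris.converged:
        return (
            float("nan"),
            float("nan"),
            RANDOM_INTERCEPT,
            "slope model did not converge",
        )
    stat = max(0.0, 2.0 * (fit_ris.loglik_reml - fit_ri.loglik_reml))
    p = lrt_mixture_pvalue(stat)
    if p < alpha:
        return stat, p, RANDOM_INTERCEPT_SLOPE, f"LRT significant (p = {p:.4g})"
    return stat, p, RANDOM_INTERCEPT, f"LRT not significant (p = {p:.4g})"


def lrt_mixture_pvalue(stat: float, naive_df2: bool = False) -> float:
    """p-value of the boundary-corrected LRT null.

    The default is 0.5*P(chi2_1 >= x) + 0.5*P(chi2_2 >= x); ``naive_df2``
    switches to the uncorrected chi-square(2) reference.
    """
    if stat <= 0:
        return 1.0
    if naive_df2:
        return float(stats.chi2.sf(stat, 2))
    return float(0.5 * stats.chi2.sf(stat, 1) + 0.5 * stats.chi2.sf(stat, 2))


def select_random_structure(
    subset: AnalysisSubset, alpha: float = 0.05, maxiter: int = 500
) -> tuple[FitResult, dict]:
    """Three-step random-structure selection for the mega-analysis.

    (1) fit the random-intercept model; (2) add a random slope for
    diagnosis; (3) compare by likelihood-ratio test.  The slope model is
    kept only when the test is significant; a non-converging slope model
    falls back to the random intercept.  Returns the chosen model's
    FitResult plus a decision trace.
    """
    fit_ri = fit_lmm(subset, MixedModelSpec(random=RANDOM_INTERCEPT), maxiter=maxiter)
    if not fit_ri.converged:
        raise EstimationError(
            "random-intercept model did not converge: no estimable mega model"
        )
    fit_ris = fit_lmm(
        subset, MixedModelSpec(random=RANDOM_INTERCEPT_SLOPE), maxiter=maxiter
    )
    stat, p, preferred, reason = lrt_random_slope(fit_ri, fit_ris, alpha=alpha)
    n1, n2 = subset.n1, subset.n2
    chosen_fit = fit_ri if preferred == RANDOM_INTERCEPT else fit_ris
    result = lmm_to_fitresult(chosen_fit, n1, n2)
    trace = {
        "ri": lmm_to_fitresult(fit_ri, n1, n2),
        "ris": lmm_to_fitresult(fit_ris, n1, n2) if fit_ris.converged else None,
        "lrt_statistic": stat,
        "lrt_p": p,
        "alpha": alpha,
        "preferred": preferred,
        "reason": reason,
    }
    return result, trace


def run_mega_lmm(
    subset: AnalysisSubset, random: str = RANDOM_INTERCEPT
) -> FitResult:
    """Fit the requested mixed model and package the diagnosis effect."""
    fit = fit_lmm(subset, MixedModelSpec(random=random))
    return lmm_to_fitresult(fit, subset.n1, subset.n2)
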