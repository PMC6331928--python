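"""Independent reference implementations used only as test oracles.

Everything here is computed by a different route than the package code:
pseudo-inverse least squares, dense grid searches, and direct dense
linear-algebra evaluation of the restricted likelihood.
"""

from __future__ import annotations

import math

import numpy as np


def ols_pinv(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients via the Moore-Penrose pseudo-inverse."""
    return np.linalg.pinv(X) @ y


def grid_tau2(
    d: np.ndarray, v: np.ndarray, step: float = 1e-5, upper: float = 1.0
) -> float:
    """Argmax of the random-effects restricted log-likelihood on a dense grid."""
    d = np.asarray(d, float)[None, :]
    v = np.asarray(v, float)[None, :]
    tau2 = np.arange(0.0, upper + step, step)[:, None]
    s = v + tau2
    w = 1.0 / s
    mu = (w * d).sum(axis=1, keepdims=True) / w.sum(axis=1, keepdims=True)
    ll = -0.5 * (
        np.log(s).sum(axis=1)
        + np.log(w.sum(axis=1))
        + (w * (d - mu) ** 2).sum(axis=1)
    )
    return float(tau2[ll.argmax(), 0])


def reml_loglik_dense(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    sigma_u2: float,
    sigma_e2: float,
) -> float:
    """Restricted log-likelihood of the random-intercept model, dense route.

    Builds V = sigma_e2*I + sigma_u2*ZZ' explicitly and evaluates
    -1/2 [ln|V| + ln|X'V^-1 X| + r'V^-1 r] - (n-p)/2 ln(2*pi), the same
    normalization statsmodels uses for its REML log-likelihood.
    """
    n, p = X.shape
    V = sigma_e2 * np.eye(n)
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        V[np.ix_(idx, idx)] += sigma_u2
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    return float(
        -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(A)[1] + r @ Vi @ r)
        - 0.5 * (n - p) * math.log(2 * math.pi)
    )


def two_group_cohens_d(y1: np.ndarray, y2: np.ndarray) -> float:
    """Plain standardized mean difference with the pooled SD."""
    n1, n2 = len(y1), len(y2)
    sp2 = ((n1 - 1) * np.var(y1, ddof=1) + (n2 - 1) * np.var(y2, ddof=1)) / (
        n1 + n2 - 2
    )
    return float((np.mean(y1) - np.mean(y2)) / math.sqrt(sp2))
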