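"""REML for the linear model with a single grouped random intercept.

y = X beta + Z gamma + eps,  gamma_g ~ N(0, sigma2_g),  eps ~ N(0, sigma2_e),

with Z the group indicator matrix.  The covariance is
sigma2_e * (I + lambda Z Z') with lambda = sigma2_g / sigma2_e, so the REML
criterion can be profiled down to a one-dimensional search over the variance
ratio lambda:

    -2 l_R(lambda) = (N - p) log sigma2_e_hat(lambda)
                     + sum_g log(1 + lambda n_g)
                     + log det(X' Vs^-1 X) + const,

where Vs = I + lambda Z Z' and sigma2_e_hat = Q(lambda) / (N - p) with Q the
GLS residual quadratic form.  Block structure makes every evaluation O(g p^2)
after one pass of per-group sufficient statistics, and a bounded scalar
minimization (tolerance 1e-10 on lambda) replaces a general optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["RandomInterceptFit", "fit_random_intercept"]

_LAMBDA_MAX = 1e8
_XATOL = 1e-10


@dataclass
class RandomInterceptFit:
    beta: np.ndarray  # fixed-effect estimates, shape (p,)
    cov_beta: np.ndarray  # fixed-effect covariance, shape (p, p)
    sigma2_group: float
    sigma2_resid: float
    lam: float  # sigma2_group / sigma2_resid
    n_obs: int
    n_groups: int
    reml_neg2loglik: float
    converged: bool = True

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def _suffstats(y, groups, X):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    codes, _ = _codes(groups)
    g = codes.max() + 1
    n = np.bincount(codes, minlength=g).astype(float)
    t = np.bincount(codes, weights=y, minlength=g)
    p = X.shape[1]
    S = np.empty((g, p))
    for j in range(p):
        S[:, j] = np.bincount(codes, weights=X[:, j], minlength=g)
    return y, X, n, t, S


def _codes(groups):
    groups = np.asarray(groups)
    uniq, codes = np.unique(groups, return_inverse=True)
    return codes, uniq


def fit_random_intercept(y, groups, X=None) -> RandomInterceptFit:
    """REML fit of a grouped random-intercept model.

    Parameters
    ----------
    y : array-like, shape (N,)
    groups : array-like, shape (N,)
        Group labels for the random intercept.
    X : array-like, shape (N, p), optional
        Fixed-effect design; defaults to an intercept column.
    """
    y = np.asarray(y, dtype=float)
    N = len(y)
    if N == 0:
        raise ValueError("empty response")
    if X is None:
        X = np.ones((N, 1))
    y, X, n, t, S = _suffstats(y, groups, X)
    p = X.shape[1]
    if N <= p:
        raise ValueError(f"need more than p={p} observations, got {N}")

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def solve_at(lam):
        c = lam / (1.0 + lam * n)  # per-group shrinkage coefficient
        M = XtX - (S * c[:, None]).T @ S
        v = Xty - S.T @ (c * t)
        q0 = yty - float(c @ (t * t))
        beta = np.linalg.solve(M, v)
        Q = q0 - float(beta @ v)
        return M, beta, max(Q, 0.0)

    def neg2reml(lam):
        M, _, Q = solve_at(lam)
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0 or Q <= 0:
            return np.inf
        s2 = Q / (N - p)
        return (N - p) * np.log(s2) + float(np.sum(np.log1p(lam * n))) + logdetM

    # lambda is unidentifiable when every group has a single observation
    identifiable = (n.max() > 1) and (len(n) > 1)
    converged = True
    if not identifiable:
        lam = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize_scalar(
                neg2reml,
                bounds=(0.0, _LAMBDA_MAX),
                method="bounded",
                options={"xatol": _XATOL},
            )
        lam = float(res.x)
        if not np.isfinite(neg2reml(lam)):
            lam, converged = 0.0, False
        elif neg2reml(0.0) <= neg2reml(lam):
            lam = 0.0

    M, beta, Q = solve_at(lam)
    s2e = Q / (N - p)
    if s2e <= 0 or not np.isfinite(s2e):
        # degenerate: no residual variation at all
        s2e = 0.0
        lam = 0.0
        M, beta, _ = solve_at(0.0)
    cov = s2e * np.linalg.inv(M) if s2e > 0 else np.zeros((p, p))
    return RandomInterceptFit(
        beta=beta,
        cov_beta=cov,
        sigma2_group=lam * s2e,
        sigma2_resid=s2e,
        lam=lam,
        n_obs=N,
        n_groups=len(n),
        reml_neg2loglik=neg2reml(lam) if s2e > 0 else -np.inf,
        converged=converged,
    )
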