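"""Synthesis of concordance results across populations.

Populations of the same species share learned song material, so their
concordances are correlated; the cross-population expectation of tau-bar is
therefore estimated with an intercept-only random-intercept model grouped by
species (REML, unweighted by default).  The directional hypothesis — Zipf's
law of abbreviation predicts a *negative* concordance — is tested one-tailed
against a t distribution with species-level degrees of freedom.

``detection_regression`` answers the planning question "how large a
repertoire do I need?": repertoire size and detection threshold are related
multiplicatively, so it regresses ln(repertoire size) on ln(-threshold) with
species random intercepts and back-transforms the fixed-part prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from ._lmm import fit_random_intercept

__all__ = [
    "PopulationEffect",
    "MetaResult",
    "meta_tau",
    "detection_regression",
    "compare_groups",
]


@dataclass(frozen=True)
class PopulationEffect:
    population_id: str
    species_id: str
    tau_bar: float
    detection_threshold: Optional[float] = None
    total_phrase_types: Optional[int] = None


@dataclass
class MetaResult:
    intercept: float
    se: float
    p_one_tailed: float  # for intercept < 0
    df: float
    sigma2_species: float
    sigma2_resid: float
    n_populations: int
    n_species: int


def meta_tau(effects, weights=None) -> MetaResult:
    """Expected tau-bar across populations, species as a random intercept.

    Parameters
    ----------
    effects : iterable of PopulationEffect
    weights : array-like, optional
        Per-population weights (e.g. inverse variances).  Default None fits
        the unweighted model.
    """
    effects = list(effects)
    tau = np.array([e.tau_bar for e in effects], dtype=float)
    sp = np.array([e.species_id for e in effects])
    if len(effects) < 2:
        raise ValueError("need at least two populations")
    n_sp = len(np.unique(sp))
    if n_sp < 2:
        warnings.warn(
            "single species: falling back to a one-sample t-test on the "
            "population concordances",
            UserWarning,
        )
        res = stats.ttest_1samp(tau, 0.0)
        df = len(tau) - 1
        t = float(res.statistic)
        return MetaResult(
            intercept=float(tau.mean()),
            se=float(tau.std(ddof=1) / np.sqrt(len(tau))),
            p_one_tailed=float(stats.t.cdf(t, df)),
            df=float(df),
            sigma2_species=0.0,
            sigma2_resid=float(tau.var(ddof=1)),
            n_populations=len(tau),
            n_species=1,
        )
    if weights is not None:
        # simple inverse-variance synthesis (off by default): weighted mean
        # with SE from the weight total; species structure is not modelled
        w = np.asarray(weights, dtype=float)
        est = float(np.sum(w * tau) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        s2_sp, s2_res = 0.0, float(np.nan)
    else:
        fit = fit_random_intercept(tau, sp)
        est = float(fit.beta[0])
        se = float(fit.se_beta[0])
        s2_sp = float(fit.sigma2_group)
        s2_res = float(fit.sigma2_resid)
    df = n_sp - 1  # species-level degrees of freedom
    t = est / se if se > 0 else -np.inf if est < 0 else np.inf
    return MetaResult(
        intercept=est,
        se=se,
        p_one_tailed=float(stats.t.cdf(t, df)),
        df=float(df),
        sigma2_species=s2_sp,
        sigma2_resid=s2_res,
        n_populations=len(tau),
        n_species=n_sp,
    )


def detection_regression(effects, predict_at):
    """Predict the repertoire size needed for significance at a given tau-bar.

    Fits ln(total_phrase_types) ~ ln(-detection_threshold) with species
    random intercepts (REML) and returns the back-transformed fixed-part
    prediction at ``predict_at`` with a 95% Wald confidence interval for the
    expectation.

    Returns
    -------
    dict with keys ``predicted``, ``ci_low``, ``ci_high``, ``slope``,
    ``intercept``, ``n``.
    """
    effects = list(effects)
    if len(effects) < 3:
        raise ValueError("need at least three populations")
    thr = np.array([e.detection_threshold for e in effects], dtype=float)
    rep = np.array([e.total_phrase_types for e in effects], dtype=float)
    sp = np.array([e.species_id for e in effects])
    if np.any(thr >= 0) or np.any(~np.isfinite(thr)):
        raise ValueError("detection thresholds must be finite and negative")
    if not predict_at < 0:
        raise ValueError("predict_at must be a negative concordance")
    x = np.log(-thr)
    y = np.log(rep)
    if np.ptp(x) == 0:
        # constant thresholds force a zero slope: intercept-only fit
        fit = fit_random_intercept(y, sp)
        fit.beta = np.array([fit.beta[0], 0.0])
        fit.cov_beta = np.pad(fit.cov_beta, ((0, 1), (0, 1)))
    else:
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_random_intercept(y, sp, X=X)
    x0 = np.array([1.0, np.log(-predict_at)])
    pred = float(x0 @ fit.beta)
    se = float(np.sqrt(x0 @ fit.cov_beta @ x0))
    z = stats.norm.ppf(0.975)
    return {
        "predicted": float(np.exp(pred)),
        "ci_low": float(np.exp(pred - z * se)),
        "ci_high": float(np.exp(pred + z * se)),
        "intercept": float(fit.beta[0]),
        "slope": float(fit.beta[1]),
        "n": len(effects),
    }


def compare_groups(group_a, group_b, alternative="two-sided"):
    """Welch two-sample t-test (unequal variances).

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    sa, sb = va / na, vb / nb
    se = np.sqrt(sa + sb)
    if se == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = float((a.mean() - b.mean()) / se)
    df = float((sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1)))
    if alternative == "two-sided":
        p = 2 * stats.t.sf(abs(t), df)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return t, df, float(p)
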