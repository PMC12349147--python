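"""Population-expected duration of each phrase type.

Birds produce individually consistent variants of shared phrase types, so
the instances of a type are clustered by bird.  The expected
(log-transformed) duration of type j in the population is therefore
estimated as the intercept of an intercept-only one-way random-intercept
model

    a_ij = abar_j + gamma_b(i) + eps_ij,
    gamma ~ N(0, sigma2_gamma_j),  eps ~ N(0, sigma2_eps_j),

fitted by REML.  The GLS intercept weights each bird by n_b/(1 + lambda n_b),
so birds that produced the type more often carry more weight, without letting
one prolific bird dominate.

Degenerate cases bypass optimization with closed forms: a single observation
yields that observation with zero variances; a single bird yields its mean
with sigma2_gamma = 0 and the sample variance as sigma2_eps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._lmm import fit_random_intercept

__all__ = ["TypeCenter", "estimate_type_center", "center_all_types"]


@dataclass
class TypeCenter:
    phrase_type: str
    a_bar_j: float
    sigma2_gamma: float
    sigma2_eps: float
    n_birds: int
    n_obs: int


def estimate_type_center(values, bird_ids, phrase_type="") -> TypeCenter:
    """REML estimate of a type's expected value and variance components."""
    values = np.asarray(values, dtype=float)
    bird_ids = np.asarray(bird_ids)
    if len(values) == 0:
        raise ValueError("empty input")
    if len(values) != len(bird_ids):
        raise ValueError("values and bird_ids must have equal length")
    uniq = np.unique(bird_ids)
    n_birds, n_obs = len(uniq), len(values)

    if n_obs == 1:
        return TypeCenter(phrase_type, float(values[0]), 0.0, 0.0, 1, 1)
    if n_birds == 1:
        return TypeCenter(
            phrase_type,
            float(values.mean()),
            0.0,
            float(values.var(ddof=1)),
            1,
            n_obs,
        )
    if np.ptp(values) == 0.0:
        return TypeCenter(phrase_type, float(values[0]), 0.0, 0.0, n_birds, n_obs)

    fit = fit_random_intercept(values, bird_ids)
    if not fit.converged:  # pragma: no cover - defensive fallback
        warnings.warn(
            f"REML did not converge for type {phrase_type!r}; "
            "falling back to the pooled mean",
            RuntimeWarning,
        )
        return TypeCenter(
            phrase_type,
            float(values.mean()),
            0.0,
            float(values.var(ddof=1)),
            n_birds,
            n_obs,
        )
    return TypeCenter(
        phrase_type,
        float(fit.beta[0]),
        float(fit.sigma2_group),
        float(fit.sigma2_resid),
        n_birds,
        n_obs,
    )


def center_all_types(pop) -> list[TypeCenter]:
    """One :class:`TypeCenter` per phrase type of a population.

    With ``pop.center == "median"`` the center is the median of per-bird
    medians (no variance components are estimated); otherwise the REML
    intercept of the one-way random-intercept model.
    """
    out = []
    if pop.center == "median":
        f = pop.count_matrix
        for j, typ in enumerate(pop.types):
            sup = f[j] > 0
            med = float(np.median(pop.bird_type_means[j, sup]))
            out.append(
                TypeCenter(str(typ), med, np.nan, np.nan, int(sup.sum()), int(f[j].sum()))
            )
        return out

    grouped = pop.records.groupby("phrase_type", sort=False)
    centers = {}
    for typ, sub in grouped:
        centers[typ] = estimate_type_center(
            sub["value"].to_numpy(), sub["bird_id"].to_numpy(), phrase_type=str(typ)
        )
    # emit in the population's type order
    for typ in pop.types:
        out.append(centers[typ])
    return out
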