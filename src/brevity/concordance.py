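"""Tie-corrected Kendall concordance and the weighted population statistic.

The per-bird statistic is Kendall's tau-b between the per-bird mean
(log-)durations and the per-bird usage counts over the bird's own repertoire.
Because tau-b computed on ``n_k`` items is a random variable with null
variance ``v_k = 2(2 n_k + 5) / (9 n_k (n_k - 1))``, birds with larger
repertoires estimate the population concordance more precisely; the
population statistic tau-bar is therefore the inverse-variance weighted mean
of the per-bird values by default (equal weighting is available).

A bird whose durations are fully tied, or whose usage counts are fully tied,
has an undefined tau-b.  Such birds are *excluded and reported*, never
scored as zero: a zero would silently shrink tau-bar toward the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "BirdConcordance",
    "kendall_tau_b",
    "tau_variance",
    "weighted_mean_tau",
]


@dataclass(frozen=True)
class BirdConcordance:
    """Per-bird concordance between duration and frequency of use."""

    bird_id: str
    n_k: int  # distinct types in the bird's repertoire
    tau_k: Optional[float]  # None when undefined (a fully tied margin)
    v_k: float  # null variance of tau for n_k items

    @property
    def defined(self) -> bool:
        return self.tau_k is not None


def kendall_tau_b(x, y):
    """Kendall's tau-b with tie corrections in both margins.

    Returns None (undefined) when either margin is fully tied; the caller
    decides how to treat undefined concordances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    tau = stats.kendalltau(x, y).statistic
    if np.isnan(tau):  # pragma: no cover - defensive
        return None
    return float(tau)


def tau_variance(n_k):
    """Null variance of Kendall's tau for a repertoire of ``n_k`` items.

    v_k = 2 (2 n_k + 5) / (9 n_k (n_k - 1)); strictly decreasing in n_k.
    """
    n_k = int(n_k)
    if n_k < 2:
        raise ValueError(f"n_k must be >= 2, got {n_k}")
    return 2.0 * (2 * n_k + 5) / (9.0 * n_k * (n_k - 1))


def bird_concordances(pop) -> list[BirdConcordance]:
    """Per-bird tau-b between bird-type mean durations and usage counts."""
    out = []
    f = pop.count_matrix
    a = pop.bird_type_means
    for k, bird in enumerate(pop.birds):
        rows = np.flatnonzero(f[:, k] > 0)
        n_k = len(rows)
        if n_k < 2:
            out.append(BirdConcordance(str(bird), n_k, None, np.nan))
            continue
        tau = kendall_tau_b(a[rows, k], f[rows, k])
        out.append(BirdConcordance(str(bird), n_k, tau, tau_variance(n_k)))
    return out


def weighted_mean_tau(concs, weights="inverse_variance"):
    """Weighted mean concordance tau-bar across birds.

    Parameters
    ----------
    concs : iterable of BirdConcordance
    weights : {"inverse_variance", "equal"}

    Birds with undefined tau are excluded.  Raises if none remain.
    """
    if weights not in ("inverse_variance", "equal"):
        raise ValueError(f"unknown weighting {weights!r}")
    taus, ws = [], []
    for c in concs:
        if not c.defined:
            continue
        taus.append(c.tau_k)
        ws.append(1.0 / c.v_k if weights == "inverse_variance" else 1.0)
    if not taus:
        raise ValueError("no bird has a defined concordance (all margins tied)")
    taus = np.asarray(taus)
    ws = np.asarray(ws)
    return float(np.sum(taus * ws) / np.sum(ws))
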