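"""Permutation test for Zipf's law of abbreviation at the individual level.

The null hypothesis is that phrase-type duration is independent of frequency
of use.  Durations are permuted among phrase types *at the population level*
(a type that receives a duration receives it in every bird that produces it),
which preserves each bird's repertoire and usage counts and therefore the
learned, non-independent structure of song within and among birds.  Each
bird's departure from the population-expected durations is preserved through
the deviation matrix D[j, k] = abar_jk - abar_j, which is added to or
subtracted from the permuted centers with equal probability — one sign per
replicate for the whole matrix, so the within- and among-bird deviation
structure survives the permutation intact.

For each replicate the per-bird Kendall tau-b values are recombined with the
same weights as the observed statistic, giving one draw tau_bar_p from the
null.  The p-value is the proportion of the null sample with
tau_bar_p <= tau_bar (no +1 correction by default).  The alpha-quantile of
the null sample is the *detection threshold*: the strength of concordance a
population of this repertoire structure would need to show before the test
can call it significant.

The inner loop is a vectorized pair-count engine: tau-b depends on the data
only through signs of pairwise differences, so per replicate it costs one
subtraction and a few bincounts over precomputed within-bird pair indices.
The observed tau_bar is computed through the same engine at the identity
permutation with the + sign, which makes the reconstruction identity exact.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .concordance import BirdConcordance, tau_variance
from .songdata import DegenerateInputError, PopulationData, build_population
from .typecenter import center_all_types

__all__ = [
    "DeviationMatrix",
    "ZLAResult",
    "ExactNull",
    "permute_centers",
    "apply_deviations",
    "zla_test",
    "exhaustive_null",
]


@dataclass
class DeviationMatrix:
    """Per-bird departures from population-expected durations.

    entries[j, k] = abar_jk - abar_j where f[j, k] > 0, NaN elsewhere.
    """

    entries: np.ndarray

    @classmethod
    def from_population(cls, pop: PopulationData, a_bar: np.ndarray) -> "DeviationMatrix":
        D = pop.bird_type_means - np.asarray(a_bar, dtype=float)[:, None]
        return cls(entries=D)


def permute_centers(a_bar, rng):
    """A uniformly random permutation of the population centers.

    The same permuted vector is assigned to every bird's column.
    """
    a_bar = np.asarray(a_bar, dtype=float)
    return a_bar[rng.permutation(len(a_bar))]


def apply_deviations(X, D, sign):
    """M = X +/- D on the support of D; one sign for the whole matrix."""
    if sign not in (1, -1):
        raise ValueError(f"sign must be +1 or -1, got {sign}")
    Dm = D.entries if isinstance(D, DeviationMatrix) else np.asarray(D, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        if len(X) != Dm.shape[0]:
            raise ValueError("length of X must match rows of D")
        X = X[:, None]
    if X.shape not in ((Dm.shape[0], 1), Dm.shape):
        raise ValueError(f"shape mismatch: X {X.shape} vs D {Dm.shape}")
    return X + sign * Dm


@dataclass
class ZLAResult:
    tau_bar: float
    null_sample: np.ndarray
    p_individual: float
    tau_pop: Optional[float]
    p_pop: Optional[float]
    detection_threshold: float
    settings: dict
    per_bird: list = field(default_factory=list)
    excluded_birds: list = field(default_factory=list)
    n_flagged_replicates: int = 0
    a_bar: Optional[np.ndarray] = None

    @property
    def significant(self) -> bool:
        return self.p_individual <= self.settings.get("alpha", 0.05)

    def to_dict(self, include_null=False) -> dict:
        d = {
            "tau_bar": self.tau_bar,
            "p_individual": self.p_individual,
            "tau_pop": self.tau_pop,
            "p_pop": self.p_pop,
            "detection_threshold": self.detection_threshold,
            "settings": self.settings,
            "per_bird": [
                {"bird_id": c.bird_id, "n_k": c.n_k, "tau_k": c.tau_k, "v_k": c.v_k}
                for c in self.per_bird
            ],
            "excluded_birds": self.excluded_birds,
            "n_flagged_replicates": self.n_flagged_replicates,
        }
        if include_null:
            d["null_sample"] = np.asarray(self.null_sample).tolist()
        return d

    def to_json(self, path, include_null=False):
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_null=include_null), fh, indent=2)


class _PairEngine:
    """Precomputed within-bird pair structure for fast tau-b evaluation."""

    def __init__(self, pop: PopulationData, a_bar: np.ndarray):
        f = pop.count_matrix
        D = pop.bird_type_means - a_bar[:, None]
        ent_type, ent_dev = [], []
        pa, pb, pair_bird, sy = [], [], [], []
        birds, n_k = [], []
        offset = 0
        for k in range(pop.b):
            rows = np.flatnonzero(f[:, k] > 0)
            if len(rows) < 2:
                continue
            idx = len(birds)
            birds.append(str(pop.birds[k]))
            n_k.append(len(rows))
            ent_type.append(rows)
            ent_dev.append(D[rows, k])
            i, j = np.triu_indices(len(rows), k=1)
            pa.append(offset + i)
            pb.append(offset + j)
            pair_bird.append(np.full(len(i), idx))
            counts = f[rows, k].astype(float)
            sy.append(np.sign(counts[i] - counts[j]))
            offset += len(rows)
        if not birds:
            raise DegenerateInputError(
                "no bird produced at least two distinct phrase types"
            )
        self.bird_ids = birds
        self.n_k = np.asarray(n_k)
        self.ent_type = np.concatenate(ent_type)
        self.ent_dev = np.concatenate(ent_dev)
        self.pa = np.concatenate(pa)
        self.pb = np.concatenate(pb)
        self.pair_bird = np.concatenate(pair_bird)
        self.sy = np.concatenate(sy)
        self.B = len(birds)
        self.n0 = np.bincount(self.pair_bird, minlength=self.B).astype(float)
        self.ty = np.bincount(
            self.pair_bird[self.sy == 0], minlength=self.B
        ).astype(float)

    def taus(self, xp, sign):
        """Per-bird tau-b for permuted centers ``xp`` and deviation sign."""
        m = xp[self.ent_type] + sign * self.ent_dev
        dx = m[self.pa] - m[self.pb]
        sx = np.sign(dx)
        num = np.bincount(self.pair_bird, weights=sx * self.sy, minlength=self.B)
        tx = np.bincount(self.pair_bird[sx == 0], minlength=self.B).astype(float)
        den2 = (self.n0 - tx) * (self.n0 - self.ty)
        with np.errstate(invalid="ignore", divide="ignore"):
            tau = np.where(den2 > 0, num / np.sqrt(den2), np.nan)
        return tau


def _pop_level_pairs(total_counts):
    n = len(total_counts)
    i, j = np.triu_indices(n, k=1)
    sy = np.sign(total_counts[i].astype(float) - total_counts[j])
    return i, j, sy


def _pop_tau(xp, i, j, sy, n0, ty):
    sx = np.sign(xp[i] - xp[j])
    tx = float(np.count_nonzero(sx == 0))
    den2 = (n0 - tx) * (n0 - ty)
    if den2 <= 0:
        return np.nan
    return float(np.sum(sx * sy) / math.sqrt(den2))


def _prepare(pop, center, scale, weights):
    if not isinstance(pop, PopulationData):
        pop = build_population(pop, scale=scale or "log", center=center or "mean")
    elif (center is not None and center != pop.center) or (
        scale is not None and scale != pop.scale
    ):
        pop = build_population(
            pop.records, scale=scale or pop.scale, center=center or pop.center
        )
    if pop.scale == "raw":
        warnings.warn(
            "analysing raw durations: among-bird variability in durations "
            "typically scales with the mean, which biases the permutation "
            "null; the log scale is recommended",
            UserWarning,
        )
    centers = center_all_types(pop)
    a_bar = np.array([c.a_bar_j for c in centers])
    engine = _PairEngine(pop, a_bar)
    obs_tau = engine.taus(a_bar, +1)  # identity permutation, + sign
    defined = ~np.isnan(obs_tau)
    if not defined.any():
        raise DegenerateInputError(
            "every bird's concordance is undefined: within each bird either "
            "all durations or all usage counts are tied"
        )
    v = np.array([tau_variance(nk) for nk in engine.n_k])
    w = (1.0 / v) if weights == "inverse_variance" else np.ones(engine.B)
    w = np.where(defined, w, 0.0)
    per_bird = [
        BirdConcordance(
            engine.bird_ids[k],
            int(engine.n_k[k]),
            float(obs_tau[k]) if defined[k] else None,
            float(v[k]),
        )
        for k in range(engine.B)
    ]
    excluded = [engine.bird_ids[k] for k in range(engine.B) if not defined[k]]
    tau_bar = float(np.sum(obs_tau[defined] * w[defined]) / np.sum(w[defined]))
    return pop, a_bar, engine, defined, w, per_bird, excluded, tau_bar


def _combine(taus, defined, w):
    """Weighted mean over the observed-defined bird set; flag if any of those
    birds has an undefined tau under this replicate."""
    ok = defined & ~np.isnan(taus)
    flagged = bool((defined & np.isnan(taus)).any())
    if not ok.any():
        return np.nan, True
    return float(np.sum(taus[ok] * w[ok]) / np.sum(w[ok])), flagged


def zla_test(
    pop,
    n_perm=10_000,
    seed=None,
    weights="inverse_variance",
    center=None,
    scale=None,
    alpha=0.05,
    p_correction=False,
) -> ZLAResult:
    """Individual-level permutation test for Zipf's law of abbreviation.

    Parameters
    ----------
    pop : PopulationData or collection of NoteRecord
    n_perm : int
        Monte-Carlo permutation count.
    seed : int, optional
        Seed for the permutation stream; fixed seed gives bit-identical
        results.
    weights : {"inverse_variance", "equal"}
        Weighting of per-bird concordances in tau-bar.
    center, scale : str, optional
        Override the population's summary ("mean"/"median") or scale
        ("log"/"raw"); defaults to the population's own settings.
    alpha : float
        Level at which the detection threshold is reported.
    p_correction : bool
        If True, report (r + 1) / (m + 1) instead of the plain proportion,
        guaranteeing a nonzero p-value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if weights not in ("inverse_variance", "equal"):
        raise ValueError(f"unknown weighting {weights!r}")
    pop, a_bar, engine, defined, w, per_bird, excluded, tau_bar = _prepare(
        pop, center, scale, weights
    )
    rng = np.random.default_rng(seed)
    n = pop.n

    fj = pop.total_counts
    i2, j2, sy2 = _pop_level_pairs(fj)
    n0_pop = float(len(i2))
    ty_pop = float(np.count_nonzero(sy2 == 0))
    tau_pop = _pop_tau(a_bar, i2, j2, sy2, n0_pop, ty_pop)
    have_pop = not np.isnan(tau_pop)

    null = np.empty(n_perm)
    null_pop = np.empty(n_perm)
    n_flagged = 0
    for r in range(n_perm):
        xp = a_bar[rng.permutation(n)]
        sign = 1 if rng.integers(0, 2) == 0 else -1
        taus = engine.taus(xp, sign)
        null[r], flagged = _combine(taus, defined, w)
        n_flagged += flagged
        null_pop[r] = _pop_tau(xp, i2, j2, sy2, n0_pop, ty_pop) if have_pop else np.nan

    valid = ~np.isnan(null)
    if not valid.any():
        raise DegenerateInputError(
            "tau_bar was undefined in every permutation replicate; the tie "
            "structure of the data leaves no usable null distribution"
        )
    r_le = int(np.sum(null[valid] <= tau_bar))
    m = int(valid.sum())
    p_ind = (r_le + 1) / (m + 1) if p_correction else r_le / m
    if have_pop:
        vp = ~np.isnan(null_pop)
        rp = int(np.sum(null_pop[vp] <= tau_pop))
        mp = int(vp.sum())
        p_pop = (rp + 1) / (mp + 1) if p_correction else rp / mp
    else:
        tau_pop, p_pop = None, None

    threshold = float(np.quantile(null[valid], alpha))
    return ZLAResult(
        tau_bar=tau_bar,
        null_sample=null,
        p_individual=float(p_ind),
        tau_pop=None if tau_pop is None else float(tau_pop),
        p_pop=None if p_pop is None else float(p_pop),
        detection_threshold=threshold,
        settings={
            "n_perm": int(n_perm),
            "seed": seed,
            "weights": weights,
            "center": pop.center,
            "scale": pop.scale,
            "alpha": float(alpha),
            "p_correction": bool(p_correction),
        },
        per_bird=per_bird,
        excluded_birds=excluded,
        n_flagged_replicates=int(n_flagged),
        a_bar=a_bar,
    )


@dataclass
class ExactNull:
    tau_bar: float
    null_sample: np.ndarray
    p_individual: float
    settings: dict


def exhaustive_null(
    pop, weights="inverse_variance", center=None, scale=None, cap=6
) -> ExactNull:
    """Exact null distribution by enumerating all n! x 2 sign-flipped
    permutations.  Feasible only for small repertoires (default cap n <= 6).
    """
    pop_, a_bar, engine, defined, w, _, _, tau_bar = _prepare(
        pop, center, scale, weights
    )
    n = pop_.n
    if math.factorial(n) * 2 > math.factorial(cap) * 2:
        raise ValueError(
            f"{n} types gives {math.factorial(n) * 2} sign-flipped "
            f"permutations, over the cap (n <= {cap}); use zla_test's "
            "Monte Carlo mode"
        )
    null = []
    for perm in itertools.permutations(range(n)):
        xp = a_bar[list(perm)]
        for sign in (+1, -1):
            taus = engine.taus(xp, sign)
            val, _ = _combine(taus, defined, w)
            null.append(val)
    null = np.asarray(null)
    valid = ~np.isnan(null)
    p = float(np.sum(null[valid] <= tau_bar) / valid.sum())
    return ExactNull(
        tau_bar=tau_bar,
        null_sample=null,
        p_individual=p,
        settings={"weights": weights, "center": pop_.center, "scale": pop_.scale},
    )
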