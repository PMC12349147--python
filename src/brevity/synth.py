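"""Synthetic song populations with controllable Zipf's-law structure.

The generator emulates the statistical structure the individual-level test
assumes about repertoire-based song:

* a population repertoire of ``n_types`` phrase types with lognormal
  durations — type centers on the log scale are Gaussian, so raw-duration
  spread among birds scales with the mean, as observed in real song;
* tutor lineages: birds within a lineage share a repertoire subset and a
  deviation profile gamma (their characteristic way of rendering each type),
  implementing learned non-independence among birds;
* per-bird usage frequencies tied to duration through a Gaussian copula with
  correlation ``effect``: 0 is the null (duration independent of use),
  negative values produce Zipf's law of abbreviation with a known mapping to
  the estimand, Kendall tau = (2 / pi) arcsin(effect);
* per-note rendition noise ``sigma_eps`` on the log scale.

Two perturbation operators emulate phrase-classification errors: merging
short types (expected to make the test conservative) and splitting long
types (expected to make it anticonservative).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .songdata import PopulationData, build_population

__all__ = ["SynthParams", "generate_population", "perturb_merge", "perturb_split"]


@dataclass(frozen=True)
class SynthParams:
    """Generator controls.

    Defaults describe a modest archive-like population: 10 annotated birds in
    5 tutor lineages drawing 10-type repertoires from a 30-type population,
    ~300 phrases per bird, type centers around exp(-1) ~ 0.37 s with a 0.4
    log-sd spread across types, 0.15 log-sd among-bird and 0.3 log-sd
    within-bird rendition variability.
    """

    n_types: int = 30
    n_birds: int = 10
    types_per_bird: int = 10
    sharing: int = 5  # number of tutor lineages
    mu_log: float = -1.0  # log-seconds
    sigma_between_types: float = 0.4
    sigma_gamma: float = 0.15  # among-bird deviation scale (log)
    sigma_eps: float = 0.3  # within-bird rendition noise (log)
    effect: float = 0.0  # copula correlation; negative = ZLA
    songs_per_bird: int = 20
    notes_per_song: int = 15
    seed: int | None = None

    def validate(self):
        if self.n_types < 2:
            raise ValueError("n_types must be >= 2")
        if self.types_per_bird > self.n_types:
            raise ValueError("types_per_bird cannot exceed n_types")
        if self.types_per_bird < 2:
            raise ValueError("types_per_bird must be >= 2")
        if not (1 <= self.sharing <= self.n_birds):
            raise ValueError("sharing must be between 1 and n_birds")
        if abs(self.effect) > 1:
            raise ValueError("|effect| must be <= 1")
        for name in ("sigma_between_types", "sigma_gamma", "sigma_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        return self


def generate_population(params: SynthParams):
    """Draw one synthetic population.

    Returns ``(pop, truth)`` where ``truth`` records every latent value the
    generator used (type centers, lineage assignments, deviation profiles,
    usage weights, and the parameters).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, b = params.n_types, params.n_birds

    a_true = params.mu_log + params.sigma_between_types * rng.standard_normal(n)
    z_a = (
        (a_true - params.mu_log) / params.sigma_between_types
        if params.sigma_between_types > 0
        else np.zeros(n)
    )

    lineage_of = np.arange(b) % params.sharing
    lineage_rep = []
    lineage_gamma = []
    for _ in range(params.sharing):
        lineage_rep.append(np.sort(rng.choice(n, params.types_per_bird, replace=False)))
        lineage_gamma.append(params.sigma_gamma * rng.standard_normal(n))

    rho = params.effect
    rows = {"bird_id": [], "phrase_type": [], "duration": []}
    weights = np.zeros((n, b))
    total_notes = params.songs_per_bird * params.notes_per_song
    for k in range(b):
        L = lineage_of[k]
        rep = lineage_rep[L]
        gamma = lineage_gamma[L]
        # Gaussian copula: usage propensity correlated rho with the (log)
        # duration center; any increasing transform preserves the ranks
        z_w = rho * z_a[rep] + np.sqrt(1 - rho**2) * rng.standard_normal(len(rep))
        w = np.exp(z_w)
        p = w / w.sum()
        weights[rep, k] = p
        counts = rng.multinomial(total_notes, p)
        for j, c in zip(rep, counts):
            if c == 0:
                continue
            logd = a_true[j] + gamma[j] + params.sigma_eps * rng.standard_normal(c)
            rows["bird_id"].extend([f"b{k:03d}"] * c)
            rows["phrase_type"].extend([f"t{j:03d}"] * c)
            rows["duration"].extend(np.exp(logd))

    df = pd.DataFrame(rows)
    df["population_id"] = "synthetic"
    df["species_id"] = "synthetic"
    pop = build_population(df)
    truth = {
        "a_bar_true": a_true,
        "lineage_of": lineage_of,
        "lineage_repertoires": lineage_rep,
        "lineage_gamma": lineage_gamma,
        "usage_weights": weights,
        "params": asdict(params),
    }
    return pop, truth


def _type_order_by_center(pop: PopulationData):
    """Type labels ordered by increasing mean transformed duration."""
    means = pop.records.groupby("phrase_type")["value"].mean()
    return means.sort_values(kind="stable").index.to_numpy(dtype=object)


def _rebuild(pop: PopulationData, df: pd.DataFrame) -> PopulationData:
    return build_population(
        df.drop(columns=["value"]), scale=pop.scale, center=pop.center
    )


def perturb_merge(pop: PopulationData, fraction, rng=None) -> PopulationData:
    """Merge a ``fraction`` of types pairwise into single labels.

    Emulates failing to distinguish similar phrase types: candidate merges
    are *adjacent* pairs in the duration ordering (only similar-duration
    types get confused), and disjoint pairs are drawn at random across the
    whole duration range until the stated fraction of types is merged.
    Durations are unchanged; frequencies pool.  Selecting merges without
    regard to where they sit in the duration range is what keeps this error
    direction-free; errors concentrated on short types instead bias the
    observed concordance itself.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    if pop.n < 3:
        raise ValueError("need at least three types to merge")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    order = _type_order_by_center(pop)
    n = pop.n
    n_pairs = int(round(fraction * n)) // 2
    used = np.zeros(n, dtype=bool)
    relabel = {}
    pairs = 0
    for s in rng.permutation(n - 1):
        if pairs >= n_pairs:
            break
        if used[s] or used[s + 1]:
            continue
        merged = f"{order[s]}+{order[s + 1]}"
        relabel[order[s]] = merged
        relabel[order[s + 1]] = merged
        used[s] = used[s + 1] = True
        pairs += 1
    if not relabel:
        return pop
    df = pop.records.copy()
    df["phrase_type"] = df["phrase_type"].map(lambda t: relabel.get(t, t))
    return _rebuild(pop, df)


def perturb_split(pop: PopulationData, fraction, rng=None) -> PopulationData:
    """Split the longest ``fraction`` of types into two daughter labels.

    Each instance of a split type is relabeled uniformly at random to one of
    two daughters, emulating spurious distinctions among long phrases.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    order = _type_order_by_center(pop)[::-1]  # longest first
    m = int(round(fraction * pop.n))
    targets = set(order[:m])
    if not targets:
        return pop
    df = pop.records.copy()
    mask = df["phrase_type"].isin(targets)
    suffix = np.where(rng.integers(0, 2, mask.sum()) == 0, "/a", "/b")
    df.loc[mask, "phrase_type"] = df.loc[mask, "phrase_type"] + suffix
    return _rebuild(pop, df)
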