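"""Per-population descriptive statistics for annotated song archives."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "PopulationSummary",
    "shannon_diversity",
    "summarize_population",
    "summarize_across",
]


@dataclass
class PopulationSummary:
    n_records: int  # annotations (birds) studied
    total_phrase_types: int
    phrases_per_record: float
    types_per_record: float
    shannon: float  # mean Shannon diversity within annotations, nats

    def to_dict(self):
        return asdict(self)


def shannon_diversity(counts):
    """Shannon diversity H = -sum p_i ln p_i of a count vector (nats)."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("need at least one positive count")
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def summarize_population(pop) -> PopulationSummary:
    """Annotation-level summary of a population.

    Shannon diversity is computed within each annotation from its phrase-type
    counts and averaged over annotations.
    """
    f = pop.count_matrix  # n types x b birds
    per_bird_totals = f.sum(axis=0)
    per_bird_types = (f > 0).sum(axis=0)
    H = np.array([shannon_diversity(f[:, k]) for k in range(pop.b)])
    return PopulationSummary(
        n_records=pop.b,
        total_phrase_types=pop.n,
        phrases_per_record=float(per_bird_totals.mean()),
        types_per_record=float(per_bird_types.mean()),
        shannon=float(H.mean()),
    )


def summarize_across(values):
    """(min, max, mean, median, sd) across populations; sd uses n-1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return {
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "sd": sd,
    }
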