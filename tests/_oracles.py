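"""Independent oracles and fixture generators shared across the test suite.

Everything here is deliberately naive (brute force, closed forms) and
independent of the package's implementation paths.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def kendall_oracle(x, y):
    """O(n^2) all-pairs Kendall tau-b with tie corrections; None if a margin
    is fully tied."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    num = n0 = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            n0 += 1
            sx = (dx > 0) - (dx < 0)
            sy = (dy > 0) - (dy < 0)
            if sx == 0:
                tx += 1
            if sy == 0:
                ty += 1
            num += sx * sy
    den2 = (n0 - tx) * (n0 - ty)
    if den2 <= 0:
        return None
    return num / math.sqrt(den2)


def welch_oracle(a, b):
    """Textbook Welch t statistic, Welch-Satterthwaite df, two-sided p."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    sa = a.var(ddof=1) / len(a)
    sb = b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return t, df, 2 * stats.t.sf(abs(t), df)


def reml_fixtures(n=50, seed=2024):
    """Seeded unbalanced one-way fixtures; frozen lme4 estimates for these
    exact fixtures live in tests/data/reml_oracle.json (keep in sync)."""
    rng = np.random.default_rng(seed)
    for _ in range(n):
        nb = int(rng.integers(3, 10))
        sizes = rng.integers(1, 12, nb)
        if (sizes > 1).sum() == 0:
            sizes[0] = 3
        g = np.repeat(np.arange(nb), sizes)
        mu = rng.normal(0, 2)
        sg = rng.uniform(0.05, 0.8)
        se = rng.uniform(0.1, 0.8)
        y = mu + rng.normal(0, sg, nb)[g] + rng.normal(0, se, len(g))
        yield y, g


def random_population(rng, max_types=5, max_birds=4, sigma_eps=0.3, min_types=2):
    """A small random population as a record DataFrame (build-ready)."""
    from brevity import build_population

    n = int(rng.integers(min_types, max_types + 1))
    b = int(rng.integers(1, max_birds + 1))
    centers = rng.normal(0.0, 0.5, n)
    rows = {"bird_id": [], "phrase_type": [], "duration": []}
    for k in range(b):
        n_k = int(rng.integers(2, n + 1))
        types = rng.choice(n, n_k, replace=False)
        for j in types:
            c = int(rng.integers(1, 6))
            d = np.exp(centers[j] + sigma_eps * rng.standard_normal(c))
            rows["bird_id"].extend([f"b{k}"] * c)
            rows["phrase_type"].extend([f"t{j}"] * c)
            rows["duration"].extend(d)
    df = pd.DataFrame(rows)
    df["population_id"] = "ranpop"
    df["species_id"] = "ransp"
    return build_population(df)
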