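import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/_oracles importable

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir():
    return DATA_DIR


def make_records(rows):
    """rows: iterable of (bird, type, duration) -> record DataFrame."""
    df = pd.DataFrame(rows, columns=["bird_id", "phrase_type", "duration"])
    df["population_id"] = "testpop"
    df["species_id"] = "testsp"
    return df


@pytest.fixture
def tiny_pop():
    """One bird, three types, frequencies strictly discordant with duration.

    Durations are exactly reproducible per type (one record each per type
    would give n_k < 2 pairs structure we want counts 3 > 2 > 1 with
    increasing durations).
    """
    from brevity import build_population

    rows = []
    for typ, dur, count in [("a", 0.2, 3), ("b", 0.4, 2), ("c", 0.8, 1)]:
        rows += [("bird1", typ, dur)] * count
    return build_population(make_records(rows))


@pytest.fixture
def two_bird_pop():
    from brevity import build_population

    rows = [
        ("b1", "x", 0.2), ("b1", "x", 0.25), ("b1", "y", 0.5),
        ("b1", "z", 0.9),
        ("b2", "x", 0.22), ("b2", "y", 0.48), ("b2", "y", 0.52),
        ("b2", "z", 1.1), ("b2", "z", 0.8),
    ]
    return build_population(make_records(rows))
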