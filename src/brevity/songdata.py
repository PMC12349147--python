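"""Ingestion, cleaning, and the per-population data model for annotated song.

The unit of observation is one produced phrase (or note): a row with a
population label, a species label, a bird (annotation) identifier, a
phrase-type label, and a duration in seconds.  All downstream statistics are
computed from two matrices derived from these rows:

* ``count_matrix`` — ``f[j, k]``, the number of times bird ``k`` produced
  phrase type ``j`` (n types x b birds, nonnegative integers), and
* ``bird_type_means`` — ``a[j, k]``, the mean (or median) log-transformed
  duration of type ``j`` as produced by bird ``k``, defined only where
  ``f[j, k] > 0`` (NaN elsewhere).

One annotation is treated as one bird: song archives typically cannot link
annotations recorded on different days to the same individual.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NoteRecord",
    "PopulationData",
    "SongDataError",
    "DegenerateInputError",
    "DEFAULT_SCHEMA",
    "read_song_table",
    "records_to_frame",
    "clean_annotations",
    "build_population",
]

#: Default column names for delimited song tables.
DEFAULT_SCHEMA = {
    "population": "population",
    "species": "species",
    "bird": "bird",
    "phrase_type": "phrase_type",
    "duration": "duration_s",
    "start": "start_s",
    "end": "end_s",
}

#: Bird-DB-style phrase-type labels: 2-3 ASCII letters.
LABEL_PATTERN = re.compile(r"^[A-Za-z]{2,3}$")


class SongDataError(ValueError):
    """Configuration or schema error in a song table."""


class DegenerateInputError(ValueError):
    """Input too degenerate for the requested statistic."""


@dataclass(frozen=True)
class NoteRecord:
    """One produced phrase instance."""

    population_id: str
    species_id: str
    bird_id: str
    phrase_type: str
    duration: float  # seconds, strictly positive
    log_duration: float = field(default=math.nan)

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if math.isnan(self.log_duration):
            object.__setattr__(self, "log_duration", math.log(self.duration))


def records_to_frame(records) -> pd.DataFrame:
    """Normalize a collection of NoteRecords (or a DataFrame) to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        required = {"population_id", "species_id", "bird_id", "phrase_type", "duration"}
        missing = required - set(records.columns)
        if missing:
            raise SongDataError(f"record frame missing columns: {sorted(missing)}")
        df = records.copy()
        if "log_duration" not in df.columns:
            df["log_duration"] = np.log(df["duration"].to_numpy(float))
        return df.reset_index(drop=True)
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "population_id",
                "species_id",
                "bird_id",
                "phrase_type",
                "duration",
                "log_duration",
            ]
        )
    return df


def read_song_table(path, schema=None, unit="duration"):
    """Read a delimited song table into a list of :class:`NoteRecord`.

    Parameters
    ----------
    path : str or path-like
        CSV or TSV file with a header row.  The delimiter is sniffed.
    schema : dict, optional
        Mapping from the logical names in :data:`DEFAULT_SCHEMA` to the
        column names used in the file.  Unmentioned keys keep their default.
    unit : {"duration", "start_end"}
        With ``"start_end"`` durations are computed as ``end - start``.

    Returns
    -------
    records : list of NoteRecord
    rejected : pandas.DataFrame
        Per-row report of rejected rows, with a ``reason`` column.
    """
    cols = dict(DEFAULT_SCHEMA)
    cols.update(schema or {})
    if unit not in ("duration", "start_end"):
        raise SongDataError(f"unit must be 'duration' or 'start_end', got {unit!r}")

    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    needed = ["population", "species", "bird", "phrase_type"]
    needed += ["start", "end"] if unit == "start_end" else ["duration"]
    missing = [cols[k] for k in needed if cols[k] not in df.columns]
    if missing:
        raise SongDataError(f"missing required column(s): {missing}")

    if unit == "start_end":
        start = pd.to_numeric(df[cols["start"]], errors="coerce")
        end = pd.to_numeric(df[cols["end"]], errors="coerce")
        duration = end - start
    else:
        duration = pd.to_numeric(df[cols["duration"]], errors="coerce")

    bad_numeric = duration.isna()
    bad_positive = ~bad_numeric & (duration <= 0)
    bad_label = df[cols["phrase_type"]].isna() | (
        df[cols["phrase_type"]].astype(str).str.strip() == ""
    )
    reasons = pd.Series("", index=df.index)
    reasons[bad_label] = "empty phrase type"
    reasons[bad_positive] = "non-positive duration"
    reasons[bad_numeric] = "missing or non-numeric duration"
    keep = reasons == ""

    rejected = df.loc[~keep].copy()
    rejected["reason"] = reasons[~keep]

    records = [
        NoteRecord(
            population_id=str(row[cols["population"]]),
            species_id=str(row[cols["species"]]),
            bird_id=str(row[cols["bird"]]),
            phrase_type=str(row[cols["phrase_type"]]).strip(),
            duration=float(d),
        )
        for (_, row), d in zip(df.loc[keep].iterrows(), duration[keep])
    ]
    return records, rejected


def clean_annotations(records, label_pattern_on=False):
    """Apply repertoire-archive cleaning rules.

    Two rules, applied in order:

    1. When ``label_pattern_on``, drop phrases whose type label is not a
       strictly alphabetic 2-3 character string (likely data-entry errors in
       Bird-DB-style archives; off by default for generic data).
    2. Drop every annotation (bird) left with fewer than two distinct phrase
       types: single-type annotations may be alarm calls, and carry no
       within-bird concordance information anyway.

    Returns ``(kept_records, report)`` where ``report`` is a JSON-serializable
    dict counting removals per rule.  Idempotent: cleaning cleaned data is a
    no-op.
    """
    df = records_to_frame(records)
    n_in = len(df)

    if label_pattern_on:
        ok = df["phrase_type"].map(lambda s: bool(LABEL_PATTERN.match(s)))
        n_bad_label = int((~ok).sum())
        df = df[ok]
    else:
        n_bad_label = 0

    types_per_bird = df.groupby("bird_id")["phrase_type"].nunique()
    single = set(types_per_bird.index[types_per_bird < 2])
    drop = df["bird_id"].isin(single)
    n_single = int(drop.sum())
    birds_removed = sorted(single)
    df = df[~drop].reset_index(drop=True)

    report = {
        "records_in": n_in,
        "records_kept": len(df),
        "removed_malformed_label": n_bad_label,
        "removed_single_type_annotation": n_single,
        "annotations_removed": birds_removed,
        "label_pattern_on": bool(label_pattern_on),
    }
    return df, report


@dataclass
class PopulationData:
    """Count and duration matrices for one population.

    Attributes
    ----------
    types : ndarray of str, shape (n,)
    birds : ndarray of str, shape (b,)
    count_matrix : ndarray of int, shape (n, b)
        ``f[j, k]``, times bird k produced type j.
    bird_type_means : ndarray of float, shape (n, b)
        ``a[j, k]``, per-bird mean (or median) transformed duration; NaN off
        the support of ``count_matrix``.
    records : pandas.DataFrame
        The kept records, with a ``value`` column holding the transformed
        duration actually analysed.
    scale, center : str
        ``"log"``/``"raw"`` and ``"mean"``/``"median"``.
    """

    types: np.ndarray
    birds: np.ndarray
    count_matrix: np.ndarray
    bird_type_means: np.ndarray
    records: pd.DataFrame
    scale: str = "log"
    center: str = "mean"

    @property
    def n(self) -> int:
        return len(self.types)

    @property
    def b(self) -> int:
        return len(self.birds)

    @property
    def total_counts(self) -> np.ndarray:
        """f[j], total instances of each type across birds."""
        return self.count_matrix.sum(axis=1)

    def validate(self):
        f = self.count_matrix
        if f.shape != (self.n, self.b):
            raise AssertionError("count matrix shape mismatch")
        if (f.sum(axis=1) < 1).any():
            raise AssertionError("every type must have at least one record")
        if (f.sum(axis=0) < 1).any():
            raise AssertionError("every bird must have at least one record")
        support = f > 0
        defined = ~np.isnan(self.bird_type_means)
        if not (support == defined).all():
            raise AssertionError("bird_type_means support must match counts")
        return self


def build_population(records, scale="log", center="mean"):
    """Aggregate records into a :class:`PopulationData`.

    ``scale="log"`` analyses natural-log durations (the default, and the
    recommended scale for durations); ``scale="raw"`` analyses raw durations.
    ``center`` selects the per-bird summary of each type's durations.
    """
    if scale not in ("log", "raw"):
        raise SongDataError(f"scale must be 'log' or 'raw', got {scale!r}")
    if center not in ("mean", "median"):
        raise SongDataError(f"center must be 'mean' or 'median', got {center!r}")
    df = records_to_frame(records)
    if df.empty:
        raise DegenerateInputError("no records")
    df = df.copy()
    df["value"] = df["log_duration"] if scale == "log" else df["duration"]

    types_per_bird = df.groupby("bird_id")["phrase_type"].nunique()
    if (types_per_bird >= 2).sum() < 1:
        raise DegenerateInputError(
            "no bird produced at least two distinct phrase types; "
            "within-bird concordance is undefined"
        )

    counts = pd.crosstab(df["phrase_type"], df["bird_id"])
    agg = "mean" if center == "mean" else "median"
    means = df.pivot_table(
        index="phrase_type", columns="bird_id", values="value", aggfunc=agg
    )
    means = means.reindex(index=counts.index, columns=counts.columns)

    return PopulationData(
        types=counts.index.to_numpy(dtype=object),
        birds=counts.columns.to_numpy(dtype=object),
        count_matrix=counts.to_numpy(dtype=np.int64),
        bird_type_means=means.to_numpy(dtype=float),
        records=df.reset_index(drop=True),
        scale=scale,
        center=center,
    ).validate()


def write_cleaning_report(report, path):
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
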