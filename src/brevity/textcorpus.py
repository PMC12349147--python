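"""Word length vs frequency concordance for plain text — the human baseline.

Zipf's law of abbreviation was first described for words, where it holds in
every language examined.  To place animal results on the same scale, this
module computes the Kendall tau-b concordance between word length (in
characters) and frequency of use across the word types of a document.

Tokenization is deliberately simple and fully documented: text is
compatibility-normalized (NFKC), case-folded, and split into maximal runs of
letter characters in any script; digits and punctuation separate tokens.
Length is the character count after normalization.  No stop-word removal and
no stemming.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

from .concordance import kendall_tau_b

__all__ = ["WordStats", "tokenize", "text_concordance"]

# maximal runs of unicode letters: \w minus digits and underscore
_WORD_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


@dataclass(frozen=True)
class WordStats:
    word: str
    length: int
    frequency: int


def tokenize(text: str) -> list[WordStats]:
    """Word types of a document with character lengths and frequencies."""
    if not isinstance(text, str):
        raise TypeError("text must be a string")
    norm = unicodedata.normalize("NFKC", text).casefold()
    counts: dict[str, int] = {}
    for tok in _WORD_RE.findall(norm):
        counts[tok] = counts.get(tok, 0) + 1
    if not counts:
        raise ValueError("no word tokens found in text")
    return [WordStats(w, len(w), c) for w, c in sorted(counts.items())]


def text_concordance(stats):
    """Kendall tau-b between word length and frequency across word types.

    Returns None (undefined) when all lengths or all frequencies are tied.
    """
    stats = list(stats)
    if len(stats) < 2:
        raise ValueError("need at least two distinct words")
    lengths = [s.length for s in stats]
    freqs = [s.frequency for s in stats]
    return kendall_tau_b(lengths, freqs)
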