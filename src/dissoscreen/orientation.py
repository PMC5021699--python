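"""Semantic orientation via pointwise mutual information (SO-PMI).

A phrase's semantic orientation is the difference between its PMI with
the positive seed word ``"excellent"`` and its PMI with the negative
seed word ``"poor"``:

    SO(phrase) = PMI(phrase, "excellent") - PMI(phrase, "poor")

PMI is estimated from term/pair presence counts over a local reference
corpus, one co-occurrence window per document (one document per line of
a plain-text file).  Add-``s`` smoothing keeps every PMI finite.  The
continuous SO value in bits is banded into the trinary code used
downstream: +1 ("excellent") above a threshold, -1 ("poor") below its
negation, 0 otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CorpusStats",
    "SOResult",
    "SEED_POSITIVE",
    "SEED_NEGATIVE",
    "DEFAULT_SMOOTHING",
    "DEFAULT_THRESHOLD",
    "count_corpus",
    "read_corpus",
    "pmi",
    "semantic_orientation",
]

SEED_POSITIVE = "excellent"
SEED_NEGATIVE = "poor"
DEFAULT_SMOOTHING = 0.5
DEFAULT_THRESHOLD = 0.5  # bits


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class CorpusStats:
    """Presence counts over co-occurrence windows of a reference corpus.

    ``term_counts[t]`` is the number of windows containing ``t`` at
    least once; ``pair_counts[(a, b)]`` (keys sorted) the number of
    windows containing both.  ``smoothing`` is the pseudo-count added to
    every count when probabilities are formed.
    """

    n_windows: int
    term_counts: dict[str, int]
    pair_counts: dict[tuple[str, str], int]
    smoothing: float = DEFAULT_SMOOTHING

    def __post_init__(self) -> None:
        if self.n_windows <= 0:
            raise ValueError("corpus must contain at least one window")
        if self.smoothing <= 0:
            raise ValueError(f"smoothing must be > 0, got {self.smoothing}")

    def term_count(self, term: str) -> int:
        return self.term_counts.get(term, 0)

    def pair_count(self, a: str, b: str) -> int:
        return self.pair_counts.get(_pair_key(a, b), 0)

    def p_term(self, term: str) -> float:
        s = self.smoothing
        return (self.term_count(term) + s) / (self.n_windows + 2 * s)

    def p_pair(self, a: str, b: str) -> float:
        s = self.smoothing
        return (self.pair_count(a, b) + s) / (self.n_windows + 2 * s)


@dataclass(frozen=True)
class SOResult:
    """SO-PMI outcome for one phrase.

    ``so == pmi_excellent - pmi_poor`` (bits); ``so_code`` is the banded
    trinary code; ``oov`` flags phrases with no in-vocabulary content
    term, which are forced to the neutral band.
    """

    pmi_excellent: float
    pmi_poor: float
    so: float
    so_code: int
    oov: bool = False
    content_terms: tuple[str, ...] = field(default_factory=tuple)


def count_corpus(
    corpus: Iterable[str | Sequence[str]],
    vocabulary: set[str] | None = None,
    smoothing: float = DEFAULT_SMOOTHING,
) -> CorpusStats:
    """Count term and pair presence per window over a document stream.

    Each document (a string, tokenized on whitespace after lowercasing,
    or an already-tokenized sequence) is one co-occurrence window; a
    term is counted at most once per window regardless of repetition.
    ``vocabulary``, when given, restricts counting to those terms (seed
    words must be included by the caller if restricted).
    """
    if smoothing <= 0:
        raise ValueError(f"smoothing must be > 0, got {smoothing}")
    n_windows = 0
    term_counts: dict[str, int] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    for doc in corpus:
        tokens = doc.lower().split() if isinstance(doc, str) else list(doc)
        present = set(tokens)
        if vocabulary is not None:
            present &= vocabulary
        n_windows += 1
        for t in present:
            term_counts[t] = term_counts.get(t, 0) + 1
        for a, b in combinations(sorted(present), 2):
            pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    if n_windows == 0:
        raise ValueError("corpus must contain at least one document")
    return CorpusStats(n_windows, term_counts, pair_counts, smoothing)


def read_corpus(path: str | Path) -> list[str]:
    """Read a reference corpus: UTF-8 text, one document per line."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def pmi(term1: str, term2: str, stats: CorpusStats) -> float:
    """Pointwise mutual information of two terms, in bits.

    ``log2(P(t1 and t2) / (P(t1) P(t2)))`` with probabilities estimated
    from smoothed presence counts; always finite, symmetric in its
    arguments, and 0 for exactly independent terms in the
    zero-smoothing limit.
    """
    return math.log2(
        stats.p_pair(term1, term2) / (stats.p_term(term1) * stats.p_term(term2))
    )


def semantic_orientation(
    phrase_tokens: Iterable[str],
    stats: CorpusStats,
    threshold: float = DEFAULT_THRESHOLD,
) -> SOResult:
    """SO-PMI of a phrase against the excellent/poor seed pair.

    The phrase is reduced to its content terms — tokens present in the
    corpus vocabulary — and each seed PMI is the mean of the token-level
    PMIs, which keeps the scale comparable across phrase lengths.  A
    phrase with no content terms is neutral and flagged ``oov``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    content = tuple(t for t in phrase_tokens if t in stats.term_counts)
    if not content:
        return SOResult(0.0, 0.0, 0.0, 0, oov=True)
    pmi_exc = sum(pmi(t, SEED_POSITIVE, stats) for t in content) / len(content)
    pmi_poor = sum(pmi(t, SEED_NEGATIVE, stats) for t in content) / len(content)
    so = pmi_exc - pmi_poor
    if so >= threshold:
        code = 1
    elif so <= -threshold:
        code = -1
    else:
        code = 0
    return SOResult(pmi_exc, pmi_poor, so, code, oov=False,
                    content_terms=content)
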