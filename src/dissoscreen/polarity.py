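"""Dictionary-based phrase polarity scoring.

The scorer assigns each phrase a signed strength on the conventional
sentiment scale of -5 (very negative) to -1 (negative) and +1 (positive)
to +5 (very positive); zero is not part of the scale.  It is driven by
three word lists:

* a *sentiment* list mapping terms to signed base strengths,
* a *booster* list of intensifiers/diminishers that shift the magnitude
  of the next sentiment-bearing word (e.g. "very" +1, "somewhat" -1),
* a *negator* list of words that flip the sign of the next sentiment
  expression including its boosters, so "not very happy" scores the
  exact negation of "very happy".

A phrase keeps a dual score — the strongest positive and the strongest
negative evidence — which is reduced to a single scalar by taking the
side with the larger magnitude; an exact tie is reported as neutral
(the scalar keeps the conventional value +1).
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Lexicon",
    "PolarityResult",
    "LexiconError",
    "tokenize",
    "load_lexicon",
    "load_default_lexicon",
    "score_phrase",
    "polarity_trinary",
]

_ALLOWED_SHIFTS = frozenset({-1, 1, 2})
_MAX_STRENGTH = 5


class LexiconError(ValueError):
    """Raised for malformed or internally inconsistent lexicon files."""


@dataclass(frozen=True)
class Lexicon:
    """Sentiment word lists: term strengths, booster shifts, negators.

    Parameters
    ----------
    sentiment
        Map from term to signed integer base strength, ``1 <= |s| <= 5``.
    boosters
        Map from term to magnitude shift in ``{-1, +1, +2}``.
    negators
        Terms that reverse the sign of the following sentiment chunk.
    """

    sentiment: Mapping[str, int]
    boosters: Mapping[str, int]
    negators: frozenset[str]

    def __post_init__(self) -> None:
        for term, s in self.sentiment.items():
            if not isinstance(s, int) or s == 0 or abs(s) > _MAX_STRENGTH:
                raise LexiconError(
                    f"sentiment strength for {term!r} must be a nonzero "
                    f"integer with magnitude <= {_MAX_STRENGTH}, got {s!r}"
                )
        for term, shift in self.boosters.items():
            if shift not in _ALLOWED_SHIFTS:
                raise LexiconError(
                    f"booster shift for {term!r} must be one of "
                    f"{sorted(_ALLOWED_SHIFTS)}, got {shift!r}"
                )
        lists = {
            "sentiment": set(self.sentiment),
            "booster": set(self.boosters),
            "negator": set(self.negators),
        }
        names = list(lists)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                dup = lists[a] & lists[b]
                if dup:
                    raise LexiconError(
                        f"terms appear in both the {a} and {b} lists: "
                        f"{sorted(dup)}"
                    )

    @property
    def n_positive(self) -> int:
        """Number of positive-strength sentiment entries."""
        return sum(1 for s in self.sentiment.values() if s > 0)

    @property
    def n_negative(self) -> int:
        """Number of negative-strength sentiment entries."""
        return sum(1 for s in self.sentiment.values() if s < 0)


@dataclass(frozen=True)
class PolarityResult:
    """Dual-score polarity of one phrase and its scalar reduction.

    ``positive_strength`` is the strongest positive evidence (>= 1,
    default 1 when no positive term matched); ``negative_strength`` the
    strongest negative evidence (<= -1, default -1).  ``scalar`` is the
    side with the larger magnitude; on a tie it is +1 and ``label`` is
    ``"neutral"``.
    """

    positive_strength: int
    negative_strength: int
    scalar: int
    label: str

    def __post_init__(self) -> None:
        assert 1 <= self.positive_strength <= _MAX_STRENGTH
        assert -_MAX_STRENGTH <= self.negative_strength <= -1
        assert self.scalar in (self.positive_strength, self.negative_strength)
        assert self.label in ("positive", "neutral", "negative")


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace, strip edge punctuation.

    No stemming or spelling correction is applied; tokens that become
    empty after stripping are dropped.
    """
    out = []
    for raw in text.lower().split():
        tok = raw.strip(string.punctuation)
        if tok:
            out.append(tok)
    return out


def _parse_term_value_file(path: Path) -> dict[str, int]:
    entries: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LexiconError(
                    f"{path}:{lineno}: expected 'term<TAB>value', got {line!r}"
                )
            term = parts[0].strip().lower()
            try:
                value = int(parts[1])
            except ValueError:
                raise LexiconError(
                    f"{path}:{lineno}: value {parts[1]!r} is not an integer"
                ) from None
            if term in entries:
                raise LexiconError(f"{path}:{lineno}: duplicate term {term!r}")
            entries[term] = value
    return entries


def _parse_term_file(path: Path) -> frozenset[str]:
    terms: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line or " " in line:
                raise LexiconError(
                    f"{path}:{lineno}: expected a single term, got {line!r}"
                )
            term = line.lower()
            if term in terms:
                raise LexiconError(f"{path}:{lineno}: duplicate term {term!r}")
            terms.add(term)
    return frozenset(terms)


def load_lexicon(
    sentiment_path: str | Path,
    booster_path: str | Path,
    negator_path: str | Path,
) -> Lexicon:
    """Load a :class:`Lexicon` from three plain-text files.

    The sentiment and booster files hold one ``term<TAB>integer`` entry
    per line; the negator file one term per line.  Lines starting with
    ``#`` are comments.  Duplicate terms within a file, terms shared
    across files, and out-of-range values raise :class:`LexiconError`
    naming the offending file and line.
    """
    return Lexicon(
        sentiment=_parse_term_value_file(Path(sentiment_path)),
        boosters=_parse_term_value_file(Path(booster_path)),
        negators=_parse_term_file(Path(negator_path)),
    )


def load_default_lexicon() -> Lexicon:
    """Load the packaged default lexicon.

    The packaged list replicates the published size of the dictionary it
    stands in for — exactly 298 positive and 465 negative entries — but
    not the original (unpublished) word list.
    """
    data = resources.files("dissoscreen") / "data"
    with resources.as_file(data) as d:
        return load_lexicon(d / "sentiment.tsv", d / "boosters.tsv",
                            d / "negators.txt")


def _effective_strengths(tokens: Sequence[str], lexicon: Lexicon) -> list[int]:
    """Signed effective strength of every sentiment-bearing token.

    For each sentiment token, the contiguous run of booster/negator
    tokens immediately before it forms its modifier chain: booster
    shifts add to the base magnitude (clamped to [1, 5]), and an odd
    number of negators flips the final sign.  Unknown tokens break the
    chain and contribute nothing.
    """
    effs: list[int] = []
    for i, tok in enumerate(tokens):
        base = lexicon.sentiment.get(tok)
        if base is None:
            continue
        shift = 0
        n_negations = 0
        j = i - 1
        while j >= 0:
            prev = tokens[j]
            if prev in lexicon.boosters:
                shift += lexicon.boosters[prev]
            elif prev in lexicon.negators:
                n_negations += 1
            else:
                break
            j -= 1
        magnitude = min(max(abs(base) + shift, 1), _MAX_STRENGTH)
        sign = 1 if base > 0 else -1
        if n_negations % 2 == 1:
            sign = -sign
        effs.append(sign * magnitude)
    return effs


def score_phrase(tokens: Iterable[str], lexicon: Lexicon) -> PolarityResult:
    """Score one tokenized phrase against a lexicon.

    Out-of-vocabulary tokens are ignored; a phrase with no sentiment
    hits (or an empty phrase) gets the neutral default (1, -1).
    """
    effs = _effective_strengths(list(tokens), lexicon)
    positive = max((e for e in effs if e > 0), default=1)
    negative = min((e for e in effs if e < 0), default=-1)
    if positive > -negative:
        label = "positive"
    elif positive < -negative:
        label = "negative"
    else:
        label = "neutral"
    scalar = positive if positive >= -negative else negative
    return PolarityResult(positive, negative, scalar, label)


def polarity_trinary(scalar: int) -> int:
    """Trinary valence level of a scalar polarity score.

    ``+1`` for scores >= +2, ``-1`` for negative scores, ``0`` for +1.
    Under the tie convention of :func:`score_phrase` the scalar +1 is
    what neutral phrases receive, so +1 is read as the neutral band;
    -1 remains an ordinary (weak) negative.
    """
    if scalar == 1:
        return 0
    return 1 if scalar > 0 else -1
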