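"""Synthetic phrase corpora with controllable channel (dis)association.

The generator emulates the structure of the screening study's data: a
control arm of 60 interviews and an impaired arm of 22 interviews, 300
phrases each.  Every phrase carries a latent valence; in the control
arm (and the non-dissociated fraction of the impaired arm) each of the
three channels — polarity, semantic orientation, tone — reproduces that
valence with probability ``concordance``, while a dissociated phrase
draws its three channel values independently of the valence and of one
another.  That is precisely the contrast the chi-square analysis and
the classifiers are meant to detect.

Phrase *text* is assembled from the polarity lexicon so that the
dictionary scorer recovers the intended polarity scalar exactly, and a
companion reference corpus ties each phrase's content words to the
"excellent"/"poor" seed words at rates that make the SO-PMI scorer
recover the intended orientation code.  Emotion labels are drawn
uniformly from the names consistent with the intended tone band.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orientation import (DEFAULT_SMOOTHING, DEFAULT_THRESHOLD,
                          SEED_NEGATIVE, SEED_POSITIVE, count_corpus,
                          semantic_orientation)
from .polarity import Lexicon, load_default_lexicon, score_phrase, tokenize
from .tone import map_emotion

__all__ = ["SynthConfig", "GeneratedDataset", "RecoveryReport",
           "generate_channels", "generate_dataset", "build_reference_corpus",
           "channel_recovery_check"]

_LEVELS = np.array([1, 0, -1])  # channel levels: positive, neutral, negative
_MAGNITUDES = np.array([1, 2, 3, 4, 5])

# function words used as inert padding; none of them may appear in the
# lexicon or the reference corpus
FILLER_WORDS = (
    "the a an and then it was we i of in at to that this there when with "
    "for from about had have my our his her their one day time said went "
    "came told asked because while after before into again"
).split()

# content-word pools for the reference corpus; each pool co-occurs with
# its seed word at a rate that fixes the sign of the SO score
EXCELLENT_POOL = (
    "orchard meadow harvest lantern violin voyage festival painting "
    "library mountain sunrise picnic melody cottage seaside harbor bakery "
    "quilt chorus fountain sculpture vineyard ballroom carousel theater "
    "garland pageant banquet serenade waltz"
).split()
POOR_POOL = (
    "basement alley ditch rust gravel smoke fog mud debt drought famine "
    "blizzard thorn swamp cellar gutter ashes weeds sewer dungeon scrap "
    "sludge cinder drizzle puddle crater rubble cobweb gristle tarpit"
).split()
NEUTRAL_POOL = (
    "table chair door street paper clock bottle pencil basket ladder "
    "carpet curtain mirror shelf bucket hallway ceiling corridor drawer "
    "napkin saucer kettle fence doormat stairs porch mailbox awning "
    "windowsill banister"
).split()

_POOL_BY_CODE = {1: EXCELLENT_POOL, 0: NEUTRAL_POOL, -1: POOR_POOL}
_EMOTIONS_BY_BAND = {1: ["joy"], 0: ["neutral"],
                     -1: ["anger", "boredom", "sadness"]}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults mirror the emulated study arm sizes.

    ``valence_distribution`` is (P(positive), P(neutral), P(negative))
    for the latent phrase valence; ``magnitude_distribution`` gives
    P(magnitude 1..5) of the polarity scalar for concordant phrases and
    ``case_magnitude_distribution`` for dissociated ones (decoupled
    speech swings to extremes, so its default is flat).  Magnitude 1 is
    excluded by default because the scorer's tie convention folds the
    +/-1 band into neutral, which would break exact text recovery.
    """

    n_control_interviews: int = 60
    n_case_interviews: int = 22
    phrases_per_interview: int = 300
    valence_distribution: tuple[float, float, float] = (0.80, 0.12, 0.08)
    concordance: float = 0.95
    dissociation: float = 1.0
    magnitude_distribution: tuple[float, ...] = (0.0, 0.45, 0.30, 0.15, 0.10)
    case_magnitude_distribution: tuple[float, ...] = (0.0, 0.10, 0.20, 0.30,
                                                      0.40)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control_interviews", "n_case_interviews",
                     "phrases_per_interview"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_control_interviews + self.n_case_interviews == 0:
            raise ValueError("at least one interview is required")
        for name, probs, k in (
                ("valence_distribution", self.valence_distribution, 3),
                ("magnitude_distribution", self.magnitude_distribution, 5),
                ("case_magnitude_distribution",
                 self.case_magnitude_distribution, 5)):
            if len(probs) != k:
                raise ValueError(f"{name} needs {k} probabilities")
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be nonnegative and sum to 1, "
                                 f"got {probs}")
        for name in ("concordance", "dissociation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class GeneratedDataset:
    """Phrase table, reference corpus and the config that produced them.

    ``phrases`` has one row per phrase with the assembled text, the
    emotion label, and the generator's intended channel values
    (``intended_polarity``, ``intended_so_code``, ``intended_tone_code``)
    as ground truth.
    """

    phrases: pd.DataFrame
    corpus: list[str]
    config: SynthConfig


@dataclass(frozen=True)
class RecoveryReport:
    """Agreement between re-scored channels and the generator's intent."""

    n: int
    polarity_agreement: float
    so_agreement: float
    tone_agreement: float


def _sample_channel(rng: np.random.Generator, valence: np.ndarray,
                    concordance: float) -> np.ndarray:
    """Each element equals its valence w.p. ``concordance``, else one of
    the other two levels uniformly."""
    n = valence.size
    agree = rng.random(n) < concordance
    # the two alternatives to each level, indexed by level value + 1
    alternatives = {1: (0, -1), 0: (1, -1), -1: (1, 0)}
    alt_pick = rng.integers(0, 2, n)
    out = valence.copy()
    flip = ~agree
    out[flip] = [alternatives[int(v)][int(j)]
                 for v, j in zip(valence[flip], alt_pick[flip])]
    return out


def generate_channels(config: SynthConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the intended channel triples only (no text or corpus).

    Fast path for simulation studies that operate directly on records.
    Returns a frame with phrase/interview ids, group, the latent
    valence, the dissociation flag and the three intended channels.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ppi = config.phrases_per_interview
    groups, interviews = [], []
    for i in range(config.n_control_interviews):
        groups += ["control"] * ppi
        interviews += [f"control-{i:03d}"] * ppi
    for i in range(config.n_case_interviews):
        groups += ["case"] * ppi
        interviews += [f"case-{i:03d}"] * ppi
    n = len(groups)
    if n == 0:
        raise ValueError("empty dataset: zero phrases requested")
    group_arr = np.array(groups)
    valence = rng.choice(_LEVELS, size=n, p=config.valence_distribution)
    dissociated = (group_arr == "case") & (rng.random(n) <
                                           config.dissociation)

    channels = {}
    for name in ("pol_level", "so_code", "tone_code"):
        conc = _sample_channel(rng, valence, config.concordance)
        indep = rng.choice(_LEVELS, size=n)
        channels[name] = np.where(dissociated, indep, conc)

    mag_conc = rng.choice(_MAGNITUDES, size=n,
                          p=config.magnitude_distribution)
    mag_diss = rng.choice(_MAGNITUDES, size=n,
                          p=config.case_magnitude_distribution)
    magnitude = np.where(dissociated, mag_diss, mag_conc)
    pol_level = channels["pol_level"]
    # neutral polarity phrases carry no sentiment term and score the
    # conventional tie scalar +1
    polarity = np.where(pol_level == 0, 1, pol_level * magnitude)

    return pd.DataFrame({
        "phrase_id": [f"{iv}-p{j % ppi:04d}"
                      for j, iv in enumerate(interviews)],
        "interview_id": interviews,
        "group": group_arr,
        "valence": valence,
        "dissociated": dissociated,
        "intended_polarity": polarity,
        "intended_so_code": channels["so_code"],
        "intended_tone_code": channels["tone_code"],
    })


def build_reference_corpus() -> list[str]:
    """Deterministic reference corpus for the SO-PMI scorer.

    Words from the excellent pool share 8 of their 10 documents with
    "excellent" and 1 with "poor" (SO of +2.50 bits at add-half
    smoothing), poor-pool words the mirror image, neutral-pool words an
    even 4/4 split (SO exactly 0).  Seed-word totals are balanced so
    the global correction term vanishes.
    """
    docs: list[str] = []
    for w in EXCELLENT_POOL:
        docs += [f"{w} {SEED_POSITIVE}"] * 8
        docs += [f"{w} {SEED_NEGATIVE}"] * 1
        docs += [w]
    for w in POOR_POOL:
        docs += [f"{w} {SEED_POSITIVE}"] * 1
        docs += [f"{w} {SEED_NEGATIVE}"] * 8
        docs += [w]
    for w in NEUTRAL_POOL:
        docs += [f"{w} {SEED_POSITIVE}"] * 4
        docs += [f"{w} {SEED_NEGATIVE}"] * 4
        docs += [w] * 2
    return docs


def _check_vocabulary(lexicon: Lexicon) -> None:
    lexicon_terms = (set(lexicon.sentiment) | set(lexicon.boosters)
                     | set(lexicon.negators))
    pools = set(EXCELLENT_POOL) | set(POOR_POOL) | set(NEUTRAL_POOL)
    reserved = pools | set(FILLER_WORDS) | {SEED_POSITIVE, SEED_NEGATIVE}
    clash = (lexicon_terms - {SEED_POSITIVE, SEED_NEGATIVE}) & reserved
    if clash:
        raise ValueError(
            "lexicon terms collide with the generator's filler/content "
            f"vocabulary: {sorted(clash)}")


def _sentiment_index(lexicon: Lexicon) -> dict[int, list[str]]:
    idx: dict[int, list[str]] = {}
    for term, s in lexicon.sentiment.items():
        if term in (SEED_POSITIVE, SEED_NEGATIVE):
            continue  # seed words live in the corpus; keep them out of text
        idx.setdefault(s, []).append(term)
    for terms in idx.values():
        terms.sort()
    return idx


def _sentiment_chunk(rng: np.random.Generator, target: int,
                     by_strength: dict[int, list[str]],
                     boosters_by_shift: dict[int, list[str]],
                     negators: list[str]) -> list[str]:
    """Token chunk whose effective polarity strength equals ``target``."""
    sign = 1 if target > 0 else -1
    mag = abs(target)
    options = []
    if by_strength.get(target):
        options.append("direct")
    if negators and by_strength.get(-target):
        options.append("negated")
    boost_opts = []
    for shift, words in boosters_by_shift.items():
        if words and 1 <= mag - shift <= 5 and by_strength.get(
                sign * (mag - shift)):
            boost_opts.append(shift)
    if boost_opts:
        options.append("boosted")
    if not options:
        raise ValueError(
            f"lexicon cannot realize polarity strength {target:+d}")
    pick = options[int(rng.integers(0, len(options)))]
    if pick == "direct":
        terms = by_strength[target]
        return [terms[int(rng.integers(0, len(terms)))]]
    if pick == "negated":
        terms = by_strength[-target]
        neg = negators[int(rng.integers(0, len(negators)))]
        return [neg, terms[int(rng.integers(0, len(terms)))]]
    shift = boost_opts[int(rng.integers(0, len(boost_opts)))]
    words = boosters_by_shift[shift]
    terms = by_strength[sign * (mag - shift)]
    return [words[int(rng.integers(0, len(words)))],
            terms[int(rng.integers(0, len(terms)))]]


def generate_dataset(config: SynthConfig,
                     lexicon: Lexicon | None = None) -> GeneratedDataset:
    """Generate the full phrase table plus its reference corpus.

    Text is assembled so that the polarity scorer recovers
    ``intended_polarity`` exactly and the SO-PMI scorer (against the
    companion corpus at default threshold) recovers
    ``intended_so_code``; the emotion label maps back to
    ``intended_tone_code`` under the default band map.
    """
    if lexicon is None:
        lexicon = load_default_lexicon()
    _check_vocabulary(lexicon)
    if config.magnitude_distribution[0] > 0 or \
            config.case_magnitude_distribution[0] > 0:
        warnings.warn(
            "magnitude-1 polarity falls in the scorer's tie band; exact "
            "polarity recovery is not guaranteed for those phrases")
    by_strength = _sentiment_index(lexicon)
    boosters_by_shift: dict[int, list[str]] = {}
    for term, shift in lexicon.boosters.items():
        boosters_by_shift.setdefault(shift, []).append(term)
    for v in boosters_by_shift.values():
        v.sort()
    negators = sorted(lexicon.negators)

    rng = np.random.default_rng(config.seed)
    frame = generate_channels(config, rng)

    texts: list[str] = []
    emotions: list[str] = []
    n_fillers = rng.integers(2, 7, size=len(frame))
    n_content = rng.integers(1, 4, size=len(frame))
    for row, nf, nc in zip(frame.itertuples(index=False), n_fillers,
                           n_content):
        items: list[list[str]] = []
        for _ in range(int(nf)):
            items.append([FILLER_WORDS[int(rng.integers(
                0, len(FILLER_WORDS)))]])
        pool = _POOL_BY_CODE[int(row.intended_so_code)]
        for _ in range(int(nc)):
            items.append([pool[int(rng.integers(0, len(pool)))]])
        if row.intended_polarity != 1:  # +1 is the neutral tie scalar
            items.append(_sentiment_chunk(rng, int(row.intended_polarity),
                                          by_strength, boosters_by_shift,
                                          negators))
        order = rng.permutation(len(items))
        texts.append(" ".join(tok for k in order for tok in items[k]))
        names = _EMOTIONS_BY_BAND[int(row.intended_tone_code)]
        emotions.append(names[int(rng.integers(0, len(names)))])

    phrases = frame.assign(text=texts, emotion=emotions)
    cols = ["phrase_id", "interview_id", "group", "text", "emotion",
            "valence", "dissociated", "intended_polarity",
            "intended_so_code", "intended_tone_code"]
    return GeneratedDataset(phrases[cols], build_reference_corpus(), config)


def channel_recovery_check(
    dataset: GeneratedDataset,
    lexicon: Lexicon | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    smoothing: float = DEFAULT_SMOOTHING,
) -> RecoveryReport:
    """Re-score the generated text with the real scorers and compare.

    Runs the dictionary polarity scorer on every phrase, the SO-PMI
    scorer against the generated reference corpus, and the tone band
    map on the emotion labels, reporting the fraction of phrases whose
    re-scored channel equals the generator's intended value.
    """
    phrases = dataset.phrases
    if len(phrases) == 0:
        raise ValueError("cannot check recovery of an empty dataset")
    if lexicon is None:
        lexicon = load_default_lexicon()
    stats = count_corpus(dataset.corpus, smoothing=smoothing)
    pol_ok = so_ok = tone_ok = 0
    for row in phrases.itertuples(index=False):
        tokens = tokenize(row.text)
        if score_phrase(tokens, lexicon).scalar == row.intended_polarity:
            pol_ok += 1
        res = semantic_orientation(tokens, stats, threshold=threshold)
        if res.so_code == row.intended_so_code:
            so_ok += 1
        if map_emotion(row.emotion) == row.intended_tone_code:
            tone_ok += 1
    n = len(phrases)
    return RecoveryReport(n, pol_ok / n, so_ok / n, tone_ok / n)
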