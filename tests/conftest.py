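import re

import pytest
from hypothesis import HealthCheck, settings

from dissoscreen import Lexicon, TrainingRecord, load_default_lexicon

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_lexicon():
    return load_default_lexicon()


@pytest.fixture()
def toy_lexicon():
    """The minimal lexicon behind the worked scoring examples."""
    return Lexicon(sentiment={"happy": 3}, boosters={"very": 1},
                   negators=frozenset({"not"}))


@pytest.fixture()
def six_term_lexicon():
    """Small lexicon for exhaustive oracle comparison."""
    return Lexicon(
        sentiment={"good": 2, "great": 4, "bad": -2, "awful": -4},
        boosters={"very": 1, "slightly": -1},
        negators=frozenset({"not"}),
    )


# the published example rows of the three-channel training file:
# 8 control rows and 12 impaired rows of (polarity, so_code, tone_code)
CONTROL_ROWS = [(3, 1, 1), (-5, -1, -1), (-5, -1, -1), (-3, -1, -1),
                (-1, -1, -1), (-4, -1, -1), (-3, 1, 1), (5, 1, 1)]
CASE_ROWS = [(5, -1, -1), (-3, 1, 0), (5, 0, 1), (5, 1, 1), (-1, 1, 1),
             (-1, 0, 1), (3, 1, -1), (5, 0, 0), (3, 1, -1), (-4, 1, 1),
             (-5, 0, 1), (5, 1, -1)]


@pytest.fixture()
def example_records():
    recs = [TrainingRecord("control", *row) for row in CONTROL_ROWS]
    recs += [TrainingRecord("case", *row) for row in CASE_ROWS]
    return recs


def brute_force_polarity(tokens, lexicon):
    """Literal re-statement of the scoring rules, used as an oracle.

    Tags the phrase as a string (S sentiment, B booster, N negator,
    O other), finds each sentiment token's modifier run with a regex,
    and applies base + shifts, clamping, and negation parity.
    """
    tags = "".join(
        "S" if t in lexicon.sentiment else
        "B" if t in lexicon.boosters else
        "N" if t in lexicon.negators else "O"
        for t in tokens
    )
    effective = []
    for m in re.finditer("S", tags):
        i = m.start()
        chain = re.search(r"[BN]*$", tags[:i]).group()
        start = i - len(chain)
        shift = sum(lexicon.boosters[tokens[j]]
                    for j in range(start, i) if chain[j - start] == "B")
        n_neg = sum(1 for j in range(start, i) if chain[j - start] == "N")
        base = lexicon.sentiment[tokens[i]]
        mag = min(5, max(1, abs(base) + shift))
        sign = (1 if base > 0 else -1) * (-1) ** n_neg
        effective.append(sign * mag)
    pos = max([e for e in effective if e > 0], default=1)
    neg = min([e for e in effective if e < 0], default=-1)
    scalar = pos if pos >= -neg else neg
    label = ("positive" if pos > -neg else
             "negative" if pos < -neg else "neutral")
    return pos, neg, scalar, label
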