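"""Dictionary polarity scorer: worked examples, file handling, properties."""

import itertools

import pytest
from hypothesis import given, strategies as st

from dissoscreen import (Lexicon, LexiconError, load_lexicon, polarity_trinary,
                         score_phrase, tokenize)

from conftest import brute_force_polarity


class TestWorkedExamples:
    def test_boosted_positive(self, toy_lexicon):
        res = score_phrase(["very", "happy"], toy_lexicon)
        assert res.scalar == 4
        assert res.label == "positive"

    def test_negated_boosted(self, toy_lexicon):
        res = score_phrase(["not", "very", "happy"], toy_lexicon)
        assert res.scalar == -4
        assert res.label == "negative"

    def test_no_hits_is_neutral(self, toy_lexicon):
        res = score_phrase(["the", "cat", "sat"], toy_lexicon)
        assert (res.positive_strength, res.negative_strength) == (1, -1)
        assert res.label == "neutral"
        assert res.scalar == 1

    def test_max_magnitude_side_wins(self):
        lex = Lexicon({"happy": 3, "terrible": -4}, {}, frozenset())
        assert score_phrase(["happy", "terrible"], lex).scalar == -4

    def test_empty_phrase(self, toy_lexicon):
        res = score_phrase([], toy_lexicon)
        assert res.label == "neutral" and res.scalar == 1


class TestScoringRules:
    def test_booster_stacking_and_clamp(self):
        lex = Lexicon({"happy": 3}, {"very": 1, "extremely": 2},
                      frozenset())
        assert score_phrase(["very", "very", "happy"], lex).scalar == 5
        # 3 + 1 + 2 clamps at the scale ceiling
        assert score_phrase(["extremely", "very", "happy"], lex).scalar == 5

    def test_diminisher_clamps_at_one(self):
        lex = Lexicon({"good": 2}, {"slightly": -1}, frozenset())
        assert score_phrase(["slightly", "slightly", "good"], lex).scalar == 1

    def test_booster_amplifies_negative_magnitude(self):
        lex = Lexicon({"awful": -3}, {"very": 1}, frozenset())
        assert score_phrase(["very", "awful"], lex).scalar == -4

    def test_unknown_token_breaks_chain(self, toy_lexicon):
        # "very" must immediately precede the sentiment word to act
        res = score_phrase(["very", "cat", "happy"], toy_lexicon)
        assert res.scalar == 3

    def test_double_negation_cancels(self, toy_lexicon):
        res = score_phrase(["not", "not", "happy"], toy_lexicon)
        assert res.scalar == 3

    def test_filler_insertion_between_chunks_is_inert(self, six_term_lexicon):
        base = score_phrase(["very", "good", "awful"], six_term_lexicon)
        padded = score_phrase(["zzz", "very", "good", "qqq", "awful"],
                              six_term_lexicon)
        assert base == padded

    def test_oracle_equivalence_exhaustive(self, six_term_lexicon):
        """All phrases of length <= 4 over the toy alphabet match a
        literal-rule brute-force enumerator."""
        alphabet = ["good", "awful", "very", "slightly", "not", "filler"]
        for n in range(5):
            for phrase in itertools.product(alphabet, repeat=n):
                res = score_phrase(list(phrase), six_term_lexicon)
                exp = brute_force_polarity(list(phrase), six_term_lexicon)
                assert (res.positive_strength, res.negative_strength,
                        res.scalar, res.label) == exp, phrase


@st.composite
def lexicon_and_term(draw):
    strength = draw(st.integers(min_value=2, max_value=5))
    sign = draw(st.sampled_from([1, -1]))
    shift = draw(st.sampled_from([None, -1, 1, 2]))
    lex = Lexicon(sentiment={"term": sign * strength},
                  boosters={} if shift is None else {"mod": shift},
                  negators=frozenset({"not"}))
    phrase = (["term"] if shift is None else ["mod", "term"])
    return lex, phrase


class TestProperties:
    @given(lexicon_and_term())
    def test_negation_antisymmetry(self, case):
        """Prepending a negator negates the scalar (outside the +/-1
        tie band, where the neutral convention absorbs the sign)."""
        lex, phrase = case
        plain = score_phrase(phrase, lex).scalar
        negated = score_phrase(["not"] + phrase, lex).scalar
        if abs(plain) >= 2:
            assert negated == -plain

    @given(st.integers(min_value=1, max_value=5))
    def test_booster_monotonicity(self, strength):
        lex = Lexicon({"term": strength}, {"very": 1}, frozenset())
        plain = score_phrase(["term"], lex).scalar
        boosted = score_phrase(["very", "term"], lex).scalar
        assert boosted >= plain
        assert abs(boosted) <= 5


class TestLexiconValidation:
    def test_strength_range(self):
        with pytest.raises(LexiconError):
            Lexicon({"happy": 6}, {}, frozenset())
        with pytest.raises(LexiconError):
            Lexicon({"happy": 0}, {}, frozenset())

    def test_booster_shift_domain(self):
        with pytest.raises(LexiconError):
            Lexicon({}, {"very": 3}, frozenset())

    def test_cross_list_duplicates_rejected(self):
        with pytest.raises(LexiconError, match="both"):
            Lexicon({"very": 2}, {"very": 1}, frozenset())
        with pytest.raises(LexiconError, match="both"):
            Lexicon({"not": 2}, {}, frozenset({"not"}))


class TestLexiconFiles:
    def test_default_lexicon_counts(self, default_lexicon):
        assert default_lexicon.n_positive == 298
        assert default_lexicon.n_negative == 465

    def test_empty_files_valid(self, tmp_path):
        for name in ("s.tsv", "b.tsv", "n.txt"):
            (tmp_path / name).write_text("# empty\n")
        lex = load_lexicon(tmp_path / "s.tsv", tmp_path / "b.tsv",
                           tmp_path / "n.txt")
        assert lex.n_positive == lex.n_negative == 0
        assert score_phrase(["anything"], lex).label == "neutral"

    def test_malformed_line_names_file_and_line(self, tmp_path):
        (tmp_path / "s.tsv").write_text("happy\t3\nbroken line here\n")
        (tmp_path / "b.tsv").write_text("")
        (tmp_path / "n.txt").write_text("")
        with pytest.raises(LexiconError, match=r"s\.tsv:2"):
            load_lexicon(tmp_path / "s.tsv", tmp_path / "b.tsv",
                         tmp_path / "n.txt")

    def test_out_of_range_strength_rejected(self, tmp_path):
        (tmp_path / "s.tsv").write_text("happy\t6\n")
        (tmp_path / "b.tsv").write_text("")
        (tmp_path / "n.txt").write_text("")
        with pytest.raises(LexiconError):
            load_lexicon(tmp_path / "s.tsv", tmp_path / "b.tsv",
                         tmp_path / "n.txt")

    def test_duplicate_within_file_rejected(self, tmp_path):
        (tmp_path / "s.tsv").write_text("happy\t3\nhappy\t2\n")
        (tmp_path / "b.tsv").write_text("")
        (tmp_path / "n.txt").write_text("")
        with pytest.raises(LexiconError, match="duplicate"):
            load_lexicon(tmp_path / "s.tsv", tmp_path / "b.tsv",
                         tmp_path / "n.txt")


class TestTokenizeAndTrinary:
    def test_tokenize_lowercases_and_strips_punctuation(self):
        assert tokenize("Very Happy!  'today'") == ["very", "happy", "today"]

    def test_tokenize_drops_pure_punctuation(self):
        assert tokenize("... -- !!") == []

    @pytest.mark.parametrize("scalar,band", [
        (5, 1), (2, 1), (1, 0), (-1, -1), (-5, -1)])
    def test_polarity_trinary_bands(self, scalar, band):
        assert polarity_trinary(scalar) == band
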