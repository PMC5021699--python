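"""Chi-square channel association, concordance, and the group report."""

import numpy as np
import pytest

from dissoscreen import (TrainingRecord, channel_association,
                         concordance_rate, dissociation_report)


def make_records(group, rows):
    return [TrainingRecord(group, *r) for r in rows]


def records_for_table(pol_level_counts):
    """Records realizing a given (polarity sign x tone) count table.

    ``pol_level_counts[(sign, tone)] = n`` with sign in {+1, -1}.
    """
    recs = []
    for (sign, tone), n in pol_level_counts.items():
        recs += make_records("g", [(3 * sign, 1, tone)] * n)
    return recs


class TestChannelAssociation:
    def test_binary_by_trinary_has_df_2(self):
        rows = [(3, 0, 1), (3, 0, 0), (3, 0, -1), (-3, 0, 1), (-3, 0, 0),
                (-3, 0, -1)] * 5
        res = channel_association(make_records("g", rows), "g",
                                  "polarity_sign", "tone_code")
        assert res.table.shape == (2, 3)
        assert res.df == 2

    def test_proportional_rows_give_zero_statistic(self):
        rows = ([(3, 0, 1)] * 10 + [(3, 0, 0)] * 10 + [(3, 0, -1)] * 10
                + [(-3, 0, 1)] * 10 + [(-3, 0, 0)] * 10 + [(-3, 0, -1)] * 10)
        res = channel_association(make_records("g", rows), "g",
                                  "polarity_sign", "tone_code")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_by_two_hand_computation(self):
        # [[30,10],[10,30]]: all expected counts 20, sum (O-E)^2/E = 20,
        # p = erfc(sqrt(10)) = 7.744e-6 for df 1
        recs = records_for_table({(-1, -1): 30, (-1, 1): 10,
                                  (1, -1): 10, (1, 1): 30})
        res = channel_association(recs, "g", "polarity_sign", "tone_code")
        assert res.df == 1
        assert res.statistic == pytest.approx(20.0, abs=1e-9)
        assert res.p_value == pytest.approx(7.744216431e-06, rel=1e-6)

    def test_transpose_invariance(self):
        rows = [(3, 1, 1), (3, -1, 0), (-2, 1, -1), (-4, -1, 1),
                (2, 1, 0), (-3, -1, -1)] * 7
        recs = make_records("g", rows)
        ab = channel_association(recs, "g", "so_code", "tone_code",
                                 collapse=False)
        ba = channel_association(recs, "g", "tone_code", "so_code",
                                 collapse=False)
        assert ab.statistic == pytest.approx(ba.statistic, rel=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, rel=1e-12)

    def test_collapse_drops_neutral_text_phrases(self):
        # polarity +1 phrases sit in the neutral band and are dropped
        rows = [(1, 0, 1)] * 10 + [(3, 0, 1)] * 5 + [(3, 0, -1)] * 5 \
            + [(-3, 0, 1)] * 5 + [(-3, 0, -1)] * 5
        res = channel_association(make_records("g", rows), "g",
                                  "polarity_sign", "tone_code")
        assert res.table.sum() == 20

    def test_full_trinary_tables_give_df_4(self):
        rows = [(p, s, t) for p in (3, 1, -3) for s in (1, 0, -1)
                for t in (1, 0, -1)] * 3
        res = channel_association(make_records("g", rows), "g",
                                  "polarity_sign", "so_code", collapse=False)
        assert res.df == 4

    def test_degenerate_single_level_raises(self):
        rows = [(3, 1, 1)] * 20
        with pytest.raises(ValueError, match="degenerate"):
            channel_association(make_records("g", rows), "g",
                                "polarity_sign", "tone_code")

    def test_empty_group_raises(self):
        recs = make_records("g", [(3, 1, 1)])
        with pytest.raises(ValueError, match="no records"):
            channel_association(recs, "other", "polarity_sign", "tone_code")

    def test_unknown_channel_raises(self):
        recs = make_records("g", [(3, 1, 1)])
        with pytest.raises(ValueError, match="unknown channel"):
            channel_association(recs, "g", "polarity", "tone_code")

    def test_small_expected_counts_warn(self):
        rows = [(3, 0, 1), (3, 0, -1), (-3, 0, 1), (-3, 0, -1)] * 2
        with pytest.warns(UserWarning, match="expected"):
            channel_association(make_records("g", rows), "g",
                                "polarity_sign", "tone_code")


class TestConcordance:
    def test_fully_concordant_rows(self):
        recs = make_records("c", [(3, 1, 1)] * 5)
        assert concordance_rate(recs) == 1.0

    def test_all_negative_agreement(self):
        assert concordance_rate(make_records("c", [(-5, -1, -1)])) == 1.0

    def test_neutral_agreement(self):
        # polarity +1 is the neutral tie scalar: all-neutral rows concur
        assert concordance_rate(make_records("c", [(1, 0, 0)])) == 1.0

    def test_published_control_rows(self, example_records):
        # hand count: 7 of the 8 control example rows are concordant
        # (the (-3, +1, +1) row disagrees in polarity sign)
        controls = [r for r in example_records if r.class_label == "control"]
        assert concordance_rate(controls) == pytest.approx(7 / 8)

    def test_published_case_rows(self, example_records):
        # hand count: only (5, 1, 1) of the 12 impaired example rows has
        # all three channels in agreement
        cases = [r for r in example_records if r.class_label == "case"]
        assert concordance_rate(cases) == pytest.approx(1 / 12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            concordance_rate([])


class TestReport:
    @pytest.fixture()
    def two_group_records(self):
        rng = np.random.default_rng(11)
        recs = []
        for group, assoc in (("control", True), ("case", False)):
            for _ in range(600):
                v = rng.choice([1, -1])
                pol = int(3 * v)
                if assoc:
                    so, tone = v, (v if rng.random() < 0.9 else -v)
                else:
                    so = int(rng.choice([1, 0, -1]))
                    tone = int(rng.choice([1, 0, -1]))
                recs.append(TrainingRecord(group, pol, so, tone))
        return recs

    def test_group_separation(self, two_group_records):
        rep = dissociation_report(two_group_records)
        for pair, res in rep.per_group["control"].items():
            assert res.p_value < 0.01, pair
        assert rep.concordance["control"] > rep.concordance["case"]

    def test_df_invariant_for_all_emitted_tables(self, two_group_records):
        rep = dissociation_report(two_group_records)
        for pairs in rep.per_group.values():
            for res in pairs.values():
                r, c = res.table.shape
                assert res.df == (r - 1) * (c - 1)

    def test_identical_groups_identical_rows(self):
        rows = [(3, 1, 1), (3, 1, -1), (-3, -1, -1), (-3, -1, 1),
                (3, -1, 0), (-3, 1, 0)] * 10
        recs = make_records("a", rows) + make_records("b", rows)
        rep = dissociation_report(recs)
        for pair in rep.per_group["a"]:
            ra, rb = rep.per_group["a"][pair], rep.per_group["b"][pair]
            assert np.array_equal(ra.table, rb.table)
            assert ra.p_value == rb.p_value

    def test_channel_vs_class_present_with_two_groups(self,
                                                      two_group_records):
        rep = dissociation_report(two_group_records)
        assert set(rep.channel_vs_class) == {"polarity_sign", "so_code",
                                             "tone_code"}

    def test_single_group_report_has_no_class_tests(self):
        rows = [(3, 1, 1), (3, 1, -1), (-3, -1, -1), (-3, -1, 1),
                (3, -1, 0), (-3, 1, 0)] * 10
        rep = dissociation_report(make_records("only", rows))
        assert rep.channel_vs_class == {}
        assert set(rep.per_group) == {"only"}

    def test_report_serializes(self, two_group_records):
        rep = dissociation_report(two_group_records)
        text = rep.to_json()
        assert "p_value" in text
        assert "control" in rep.to_text()
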