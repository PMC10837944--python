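import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from akicomorbid import (
    AKI_ITEM,
    MiningThresholds,
    PairRule,
    ReferencePairSet,
    ValidationVerdict,
    chi_square_2x2,
    confirm_by_membership,
    consistency_table,
    fallback_match,
    validate_pairs,
)

from .conftest import make_transactions


def closed_form_chi2(a, b, c, d):
    """Oracle: N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestMembership:
    def test_unordered_match(self):
        ref = ReferencePairSet(source="eicu", pairs={("I10", "N17")})
        flags = confirm_by_membership([("N17", "I10")], ref)
        assert flags[("I10", "N17")] is True

    def test_absent_pair(self):
        ref = ReferencePairSet(source="eicu", pairs={("I10", "N17")})
        assert confirm_by_membership([("E78", "N17")], ref)[("E78", "N17")] is False

    def test_empty_reference(self):
        ref = ReferencePairSet(source="eicu")
        flags = confirm_by_membership([("A00", "B00"), ("C00", "D00")], ref)
        assert not any(flags.values())

    def test_monotone_under_reference_growth(self):
        small = ReferencePairSet(source="r", pairs={("A00", "B00")})
        big = ReferencePairSet(source="r", pairs={("A00", "B00"), ("C00", "D00")})
        pairs = [("A00", "B00"), ("C00", "D00"), ("E00", "F00")]
        f_small = confirm_by_membership(pairs, small)
        f_big = confirm_by_membership(pairs, big)
        assert all(f_big[p] for p in f_small if f_small[p])


class TestChiSquare:
    def test_worked_example(self):
        stat, p = chi_square_2x2(30, 20, 10, 40)
        assert stat == pytest.approx(16.667, abs=1e-3)
        assert p < 0.05

    def test_proportional_table_is_zero(self):
        stat, p = chi_square_2x2(10, 10, 10, 10)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_undefined(self):
        assert chi_square_2x2(0, 0, 5, 5) == (None, None)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(-1, 2, 3, 4)

    @given(
        a=st.integers(0, 200), b=st.integers(0, 200),
        c=st.integers(0, 200), d=st.integers(0, 200),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_closed_form(self, a, b, c, d):
        stat, p = chi_square_2x2(a, b, c, d)
        margins = (a + b, c + d, a + c, b + d)
        if any(m == 0 for m in margins):
            assert (stat, p) == (None, None)
        else:
            expected = closed_form_chi2(a, b, c, d)
            assert stat == pytest.approx(expected, rel=1e-9)
            assert p == pytest.approx(stats.chi2.sf(expected, df=1), rel=1e-9)


def s09_fixture():
    """20 patients; S09 fails ID-3 concept mapping but its ID-4 expansion
    S091 is mappable and significantly co-occurrent in the reference."""
    items = {}
    full_codes = {}
    for i in range(20):
        pid = f"P{i:02d}"
        itemset = {"I10", "E78"}
        codes = {"I10", "E785"}
        if i < 10:
            itemset.add(AKI_ITEM)
        if i < 8 or i in (10, 11):  # S09 in 8 AKI + 2 non-AKI patients
            itemset.add("S09")
            codes.update({"S0911", "S0931"})
        items[pid] = frozenset(itemset)
        full_codes[pid] = codes
    transactions = make_transactions(items)
    reference = ReferencePairSet(
        source="cohd",
        concept_map={"I10": "c1", "E78": "c2", "S091": "c3", "S093": "c4"},
        cooccurrence={
            (AKI_ITEM, "S091"): (30, 20, 10, 40),  # significant
            (AKI_ITEM, "S093"): (10, 10, 10, 10),  # chi2 = 0, not significant
        },
    )
    return transactions, full_codes, reference


class TestFallback:
    def test_s09_confirmed_via_id4(self):
        tx, full, ref = s09_fixture()
        verdict = fallback_match(
            (AKI_ITEM, "S09"), ref, tx, full, MiningThresholds(min_sup=0.1)
        )
        assert verdict.confirmed_by["cohd"] is True
        assert verdict.matched_level == "ID4"
        assert verdict.final == "confirmed"

    def test_mapped_partner_skips_fallback(self):
        tx, full, ref = s09_fixture()
        ref.cooccurrence[(AKI_ITEM, "I10")] = (30, 20, 10, 40)
        verdict = fallback_match((AKI_ITEM, "I10"), ref, tx, full)
        assert verdict.matched_level == "ID3"
        assert verdict.confirmed_by["cohd"] is True

    def test_descends_to_id5_when_id4_unmapped(self):
        tx, full, ref = s09_fixture()
        ref.concept_map.pop("S091")
        ref.concept_map.pop("S093")
        ref.concept_map["S0911"] = "c5"
        ref.cooccurrence[(AKI_ITEM, "S0911")] = (30, 20, 10, 40)
        verdict = fallback_match(
            (AKI_ITEM, "S09"), ref, tx, full, MiningThresholds(min_sup=0.1)
        )
        assert verdict.matched_level == "ID5"
        assert verdict.confirmed_by["cohd"] is True

    def test_no_expansions_unconfirmed(self):
        tx, full, ref = s09_fixture()
        stripped = {pid: {c for c in codes if not c.startswith("S09")}
                    for pid, codes in full.items()}
        verdict = fallback_match(
            (AKI_ITEM, "S09"), ref, tx, stripped, MiningThresholds(min_sup=0.1)
        )
        assert verdict.matched_level == "none"
        assert verdict.final == "unconfirmed"

    def test_insignificant_reference_not_confirmed(self):
        tx, full, ref = s09_fixture()
        ref.cooccurrence[(AKI_ITEM, "S091")] = (10, 10, 10, 10)
        verdict = fallback_match(
            (AKI_ITEM, "S09"), ref, tx, full, MiningThresholds(min_sup=0.1)
        )
        assert verdict.final == "unconfirmed"

    def test_fallback_does_not_change_mapped_verdicts(self):
        tx, full, ref = s09_fixture()
        ref.cooccurrence[(AKI_ITEM, "E78")] = (30, 20, 10, 40)
        before = fallback_match((AKI_ITEM, "E78"), ref, tx, full)
        richer = {pid: codes | {"E7801"} for pid, codes in full.items()}
        after = fallback_match((AKI_ITEM, "E78"), ref, tx, richer)
        assert before.matched_level == after.matched_level == "ID3"
        assert before.confirmed_by == after.confirmed_by


class TestValidatePairs:
    def test_final_confirmed_iff_any_source(self):
        rule = PairRule(item_a=AKI_ITEM, item_b="I10", n_a=10, n_b=12, n_ab=8, n_total=20)
        membership = ReferencePairSet(source="eicu", pairs={(AKI_ITEM, "I10")})
        verdicts = validate_pairs([rule], membership_ref=membership)
        assert verdicts[0].final == "confirmed"
        empty = ReferencePairSet(source="eicu")
        verdicts = validate_pairs([rule], membership_ref=empty)
        assert verdicts[0].final == "unconfirmed"


class TestConsistencyTable:
    def _verdict(self, pair, a, b):
        return ValidationVerdict(pair=pair, confirmed_by={"eicu": a, "cohd": b})

    def test_direct_tabulation(self):
        verdicts = [
            self._verdict(("A00", "B00"), True, True),
            self._verdict(("A00", "C00"), True, False),
            self._verdict(("A00", "D00"), False, False),
        ]
        table = consistency_table(verdicts, "eicu", "cohd")
        assert (table["yes_yes"], table["yes_no"], table["no_yes"], table["no_no"]) == (1, 1, 0, 1)
        assert table["total"] == 3

    def test_all_confirmed(self):
        verdicts = [self._verdict(("A00", f"B{i:02d}"), True, True) for i in range(5)]
        table = consistency_table(verdicts, "eicu", "cohd")
        assert table["yes_yes"] == table["total"] == 5

    def test_empty(self):
        table = consistency_table([], "eicu", "cohd")
        assert table["total"] == 0 and table["yes_yes"] == 0

    def test_literature_split_of_residual(self):
        verdicts = [
            self._verdict(("A00", "B00"), False, False),
            self._verdict(("A00", "C00"), False, False),
        ]
        table = consistency_table(
            verdicts, "eicu", "cohd", literature_flags={("A00", "B00"): True}
        )
        assert table["literature_yes"] == 1 and table["literature_no"] == 1

    @given(
        flags=st.lists(st.tuples(st.booleans(), st.booleans()), max_size=30)
    )
    def test_margins_sum_to_total(self, flags):
        verdicts = [
            self._verdict(("A00", f"B{i:02d}"), a, b) for i, (a, b) in enumerate(flags)
        ]
        table = consistency_table(verdicts, "eicu", "cohd")
        cells = table["yes_yes"] + table["yes_no"] + table["no_yes"] + table["no_no"]
        assert cells == table["total"] == len(flags)
        assert table["literature_yes"] + table["literature_no"] == table["no_no"]
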