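import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neuroagree.agreement import (
    AgreementUnit,
    MatchConfig,
    agreement_result,
    build_units,
    cohen_kappa,
    concordance,
    expected_agreement,
    match_spans,
    observed_agreement,
    pairwise_agreement,
)
from neuroagree.annotation_model import AnnotationSet, CategoryLabel, Screen

from conftest import contingency_kappa, make_units, random_units, span


class TestMatchSpans:
    def setup_method(self):
        self.screen = Screen("n", 0, "imbalance and leg weakness with back pain today")

    def test_identical_offsets_match(self):
        a = [span(self.screen, 0, 9)]
        b = [span(self.screen, 0, 9)]
        matched, a_only, b_only = match_spans(a, b)
        assert len(matched) == 1 and not a_only and not b_only

    def test_unmatched_span_is_singleton(self):
        a = [span(self.screen, 0, 9)]
        matched, a_only, b_only = match_spans(a, [])
        assert not matched and a_only == a and not b_only

    def test_exact_mode_rejects_near_miss(self):
        a = [span(self.screen, 14, 26)]
        b = [span(self.screen, 14, 22)]
        matched, a_only, b_only = match_spans(a, b, MatchConfig(mode="exact"))
        assert not matched and len(a_only) == 1 and len(b_only) == 1

    def test_overlap_mode_pairs_near_miss(self):
        a = [span(self.screen, 14, 26)]
        b = [span(self.screen, 14, 22)]
        matched, a_only, b_only = match_spans(a, b, MatchConfig(mode="overlap"))
        assert len(matched) == 1 and not a_only and not b_only

    def test_overlap_mode_prefers_maximal_overlap(self):
        a = [span(self.screen, 14, 26)]
        b = [span(self.screen, 24, 30), span(self.screen, 14, 26)]
        matched, _, b_only = match_spans(a, b, MatchConfig(mode="overlap"))
        assert matched[0][1].key == (14, 26)
        assert b_only[0].key == (24, 30)

    @given(
        st.lists(st.integers(0, 20), min_size=0, max_size=6),
        st.lists(st.integers(0, 20), min_size=0, max_size=6),
        st.sampled_from(["exact", "overlap"]),
    )
    def test_partition_is_exhaustive_and_disjoint(self, starts_a, starts_b, mode):
        text = "x" * 50
        screen = Screen("n", 0, text)
        # non-overlapping spans of width 2 at even offsets
        a = [span(screen, 2 * s, 2 * s + 2) for s in sorted(set(starts_a))]
        b = [span(screen, 2 * s, 2 * s + 2) for s in sorted(set(starts_b))]
        matched, a_only, b_only = match_spans(a, b, MatchConfig(mode=mode))
        assert len(matched) + len(a_only) == len(a)
        assert len(matched) + len(b_only) == len(b)
        seen_a = [m[0] for m in matched] + a_only
        assert sorted(s.key for s in seen_a) == sorted(s.key for s in a)


class TestBuildUnits:
    def setup_method(self):
        self.screens = [
            Screen("n", 0, "imbalance with leg weakness and pain"),
            Screen("n", 1, "No complaints."),
        ]

    def test_null_screen_contributes_one_agreeing_unit(self):
        empty_a = AnnotationSet("A", {})
        empty_b = AnnotationSet("B", {})
        units = build_units(empty_a, empty_b, self.screens, "span")
        assert len(units) == 2
        assert all(u.unit_kind == "null_screen_unit" and u.agrees() for u in units)

    def test_three_shared_spans_give_three_agreeing_units(self):
        screen = self.screens[0]
        spans = [span(screen, 0, 9), span(screen, 15, 27, CategoryLabel.BIGRAM),
                 span(screen, 32, 36)]
        set_a = AnnotationSet("A", {screen.key: spans})
        set_b = AnnotationSet("B", {screen.key: list(spans)})
        units = build_units(set_a, set_b, [screen], "span")
        assert len(units) == 3
        assert all(u.unit_kind == "span_unit" and u.agrees() for u in units)

    def test_singleton_is_present_vs_null(self):
        screen = self.screens[0]
        set_a = AnnotationSet("A", {screen.key: [span(screen, 0, 9)]})
        set_b = AnnotationSet("B", {})
        units = build_units(set_a, set_b, [screen], "span")
        span_units = [u for u in units if u.unit_kind == "span_unit"]
        assert len(span_units) == 1
        assert (span_units[0].rating_a, span_units[0].rating_b) == ("present", "null")

    def test_label_task_rates_with_category_labels(self):
        screen = self.screens[0]
        sa = span(screen, 0, 9, CategoryLabel.UNIGRAM)
        sb = span(screen, 0, 9, CategoryLabel.BIGRAM)
        set_a = AnnotationSet("A", {screen.key: [sa]})
        set_b = AnnotationSet("B", {screen.key: [sb]})
        (unit, null_unit) = build_units(set_a, set_b, self.screens, "label")
        assert (unit.rating_a, unit.rating_b) == ("unigram", "bigram")
        assert not unit.agrees()

    def test_unit_count_identity(self):
        """n_units = |A ∪ B| + null screens, per the denominator definition."""
        screen = self.screens[0]
        set_a = AnnotationSet("A", {screen.key: [span(screen, 0, 9), span(screen, 32, 36)]})
        set_b = AnnotationSet("B", {screen.key: [span(screen, 0, 9),
                                                 span(screen, 15, 27, CategoryLabel.BIGRAM)]})
        units = build_units(set_a, set_b, self.screens, "span")
        union = {(0, 9), (32, 36), (15, 27)}
        n_null = 1
        assert len(units) == len(union) + n_null

    def test_stray_screen_rejected(self):
        set_a = AnnotationSet("A", {("ghost", 7): []})
        with pytest.raises(Exception, match="ghost"):
            build_units(set_a, AnnotationSet("B", {}), self.screens, "span")


class TestHandWorkedConfiguration:
    """8 both-present + 1 a-only + 1 b-only + 10 null screens (20 units)."""

    def setup_method(self):
        self.units = make_units(n_both=8, n_a_only=1, n_b_only=1, n_null=10)

    def test_observed_agreement(self):
        assert observed_agreement(self.units) == pytest.approx(0.900, abs=1e-12)

    def test_expected_agreement_from_marginals(self):
        # each rater: 9/20 present, 11/20 null -> 0.45^2 + 0.55^2
        assert expected_agreement(self.units) == pytest.approx(0.505, abs=1e-12)

    def test_kappa(self):
        assert cohen_kappa(self.units) == pytest.approx((0.9 - 0.505) / 0.495, abs=1e-12)
        assert cohen_kappa(self.units) == pytest.approx(0.798, abs=5e-4)

    def test_concordance(self):
        assert concordance(self.units) == pytest.approx(90.0, abs=1e-12)

    def test_denominator(self):
        assert len(self.units) == 20


class TestKappaProperties:
    def test_matches_contingency_oracle_on_random_unit_lists(self):
        rng = np.random.default_rng(20240917)
        checked = 0
        while checked < 200:
            n = int(rng.integers(2, 120))
            cats = ["null", "present", "unigram", "bigram"][: int(rng.integers(2, 5))]
            units = random_units(rng, n, cats)
            po_o, pe_o, k_o = contingency_kappa(units)
            assert observed_agreement(units) == pytest.approx(po_o, abs=1e-12)
            assert expected_agreement(units) == pytest.approx(pe_o, abs=1e-12)
            if pe_o < 1.0 - 1e-12:
                assert cohen_kappa(units) == pytest.approx(k_o, abs=1e-12)
            checked += 1

    def test_symmetry_under_rater_swap(self):
        rng = np.random.default_rng(7)
        units = random_units(rng, 300, ["null", "present", "unigram"])
        swapped = [
            AgreementUnit(u.screen_key, u.unit_kind, u.span_key, u.rating_b, u.rating_a)
            for u in units
        ]
        assert observed_agreement(units) == pytest.approx(observed_agreement(swapped))
        assert expected_agreement(units) == pytest.approx(expected_agreement(swapped))
        assert cohen_kappa(units) == pytest.approx(cohen_kappa(swapped))

    def test_perfect_agreement_gives_kappa_one(self):
        units = make_units(n_both=5, n_null=5)
        assert cohen_kappa(units) == pytest.approx(1.0)
        assert concordance(units) == pytest.approx(100.0)

    def test_independent_raters_give_kappa_near_zero(self):
        rng = np.random.default_rng(11)
        units = []
        for i in range(5000):
            ra = "present" if rng.random() < 0.5 else "null"
            rb = "present" if rng.random() < 0.5 else "null"
            kind = "null_screen_unit" if ra == rb == "null" else "span_unit"
            units.append(AgreementUnit(("n", i), kind, None, ra, rb))
        assert abs(cohen_kappa(units)) < 0.05

    def test_degenerate_all_agreeing_constant_returns_one_with_warning(self):
        units = make_units(n_null=4)
        with pytest.warns(UserWarning, match="convention"):
            assert cohen_kappa(units) == 1.0

    def test_opposite_constant_raters_give_zero_chance_agreement(self):
        # A always "present", B always "null": no category shared -> pe = 0
        units = [
            AgreementUnit(("n", 0), "span_unit", (0, 5), "present", "null"),
            AgreementUnit(("n", 1), "span_unit", (0, 5), "present", "null"),
        ]
        assert expected_agreement(units) == 0.0
        assert cohen_kappa(units) == 0.0

    def test_empty_unit_list_rejected(self):
        with pytest.raises(ValueError):
            observed_agreement([])

    @given(st.integers(1, 30), st.integers(0, 10), st.integers(1, 40))
    def test_adding_agreeing_null_units_never_lowers_concordance(
        self, n_both, n_disagree, n_added
    ):
        base = make_units(n_both=n_both, n_a_only=n_disagree)
        before = concordance(base)
        after = concordance(base + make_units(n_null=n_added))
        assert after >= before - 1e-12


class TestPairwise:
    def _sets(self, n_raters):
        screens = [Screen("n", 0, "imbalance noted on exam"), Screen("n", 1, "stable")]
        sets = []
        for i in range(n_raters):
            sets.append(AnnotationSet(f"R{i}", {screens[0].key: [span(screens[0], 0, 9)]}))
        return sets, screens

    def test_three_raters_give_three_pairs(self):
        sets, screens = self._sets(3)
        results = pairwise_agreement(sets, screens, "span")
        assert len(results) == 3

    def test_four_raters_give_six_pairs(self):
        sets, screens = self._sets(4)
        results = pairwise_agreement(sets, screens, "span")
        assert len(results) == 6

    def test_duplicated_sets_all_kappa_one(self):
        screens = [Screen("n", 0, "imbalance noted on exam"), Screen("n", 1, "stable")]
        base = {("n", 0): [span(screens[0], 0, 9)]}
        sets = [AnnotationSet(r, dict(base)) for r in ("A", "B", "C")]
        results = pairwise_agreement(sets, screens, "span")
        assert all(res.kappa == pytest.approx(1.0) for res in results.values())

    def test_fewer_than_two_sets_rejected(self):
        sets, screens = self._sets(1)
        with pytest.raises(ValueError):
            pairwise_agreement(sets, screens, "span")

    def test_result_consistency(self):
        sets, screens = self._sets(2)
        res = next(iter(pairwise_agreement(sets, screens, "span").values()))
        assert res.concordance_pct == pytest.approx(100 * res.po)
        assert res.kappa == pytest.approx((res.po - res.pe) / (1 - res.pe))
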