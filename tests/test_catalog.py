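import numpy as np
import pytest

from riboassoc.catalog import (
    Contingency2x2,
    classify_catalog,
    compare_groups,
    composite_scores,
    enrichment_test,
    rai,
    select_trans,
    tissue_specificity,
    translation_score,
)
from riboassoc.errors import DataError


class TestTissueSpecificity:
    @pytest.mark.parametrize("x,m,expected", [(10, 10, 0.0), (1, 10, 1.0), (4, 10, 2 / 3)])
    def test_examples(self, x, m, expected):
        assert tissue_specificity(x, m) == pytest.approx(expected)

    def test_unexpressed_everywhere_undefined(self):
        with pytest.raises(DataError):
            tissue_specificity(0, 10)

    def test_single_dataset_denominator_guard(self):
        with pytest.raises(DataError):
            tissue_specificity(1, 1)


class TestRai:
    def test_partial_association(self):
        x = [1, 1, 1, 1, 0]
        y = [1, 1, 1, -1, 0]
        assert rai(x, y) == pytest.approx(0.5)

    def test_bounds(self):
        assert rai([1, 1], [1, 1]) == 1.0
        assert rai([1, 1], [-1, -1]) == -1.0

    def test_unexpressed_everywhere_is_error(self):
        with pytest.raises(DataError):
            rai([0, 0], [0, 0])

    def test_invariant_under_permutation_and_padding(self, rng):
        x = [1, 0, 1, 1, 0, 1]
        y = [1, 0, -1, 1, 0, 1]
        base = rai(x, y)
        perm = rng.permutation(len(x))
        assert rai(np.array(x)[perm], np.array(y)[perm]) == pytest.approx(base)
        # an extra dataset where the lncRNA is unexpressed changes nothing
        assert rai(x + [0], y + [0]) == pytest.approx(base)


class TestCompositeScores:
    @pytest.mark.parametrize(
        "r,s,expected",
        [
            (1.0, 0.0, (1.0, 0.0)),
            (0.5, 2 / 3, (1 / 6, 1 / 3)),
            (-1.0, 0.0, (-1.0, 0.0)),
        ],
    )
    def test_examples(self, r, s, expected):
        assert composite_scores(r, s) == pytest.approx(expected)

    def test_composites_sum_to_rai(self, rng):
        for _ in range(50):
            r, s = rng.uniform(-1, 1), rng.uniform(0, 1)
            u, v = composite_scores(r, s)
            assert u + v == pytest.approx(r)
            assert -1 - 1e-12 <= u <= 1 + 1e-12 and -1 - 1e-12 <= v <= 1 + 1e-12


class TestClassifyCatalog:
    def test_percentile_thresholds(self):
        labels = classify_catalog(list(range(1, 21)))
        assert labels[0] == "noribo"  # 1 < 1.95
        assert labels[-1] == "ribo"  # 20 > 19.05
        assert labels[9] == "other"

    def test_all_equal_yields_no_extremes(self):
        labels = classify_catalog([0.3] * 25)
        assert set(labels) == {"other"}

    def test_value_at_threshold_stays_other(self):
        scores = list(range(21))  # percentiles land exactly on 1 and 19
        assert np.percentile(scores, [5, 95]) == pytest.approx([1.0, 19.0])
        labels = classify_catalog(scores)
        assert labels[0] == "noribo" and labels[20] == "ribo"
        assert labels[1] == "other" and labels[19] == "other"

    def test_too_few_entries_is_hard_error(self):
        with pytest.raises(DataError):
            classify_catalog([0.1] * 19)

    def test_extreme_fractions_bounded(self, rng):
        scores = rng.normal(size=400)
        labels = classify_catalog(scores)
        n = len(scores)
        assert labels.count("noribo") <= 0.05 * n + 1
        assert labels.count("ribo") <= 0.05 * n + 1


class TestTranslationScore:
    @pytest.mark.parametrize(
        "levels,expected",
        [((3, 3), 2.0), ((0,), -1.0), ((3,) * 9 + (2,), 9.5), ((1, 2), 0.0)],
    )
    def test_weighted_sum(self, levels, expected):
        assert translation_score(list(levels)) == pytest.approx(expected)

    def test_no_associated_dataset_is_error(self):
        with pytest.raises(DataError):
            translation_score([])


class TestSelectTrans:
    def test_top_five_percent(self):
        flags = select_trans(list(range(1, 101)))
        assert [v for v, f in zip(range(1, 101), flags) if f] == [96, 97, 98, 99, 100]

    def test_all_equal_selects_none(self):
        assert not any(select_trans([2.0] * 40))

    def test_single_value_not_relabelled(self):
        assert select_trans([5.0]) == [False]


class TestEnrichmentTest:
    def test_proportional_rows_ratio_one(self):
        res = enrichment_test(Contingency2x2(10, 90, 100, 900))
        assert res.ratio == pytest.approx(1.0)
        assert res.p_value > 0.4

    def test_zero_margin_degenerate(self):
        res = enrichment_test(Contingency2x2(0, 0, 3, 7))
        assert np.isnan(res.ratio)
        assert res.p_value == 1.0

    def test_strong_enrichment_detected(self):
        res = enrichment_test(Contingency2x2(20, 10, 10, 200))
        assert res.ratio > 5
        assert res.odds_ratio > 5
        assert res.p_value < 1e-6

    def test_negative_cell_rejected(self):
        with pytest.raises(DataError):
            Contingency2x2(-1, 2, 3, 4)


class TestCompareGroups:
    def test_identical_groups(self):
        stat, p, (ma, mb) = compare_groups([1, 2, 3], [1, 2, 3])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert ma == mb

    def test_shift_recovered_in_means(self, rng):
        a = rng.normal(size=500)
        b = a + 1.5
        _, _, (ma, mb) = compare_groups(a, b)
        assert mb - ma == pytest.approx(1.5)

    def test_welch_matches_hand_computation(self):
        # frozen from the textbook Welch formula on this 5+5 fixture
        stat, p, _ = compare_groups([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], method="welch")
        assert stat == pytest.approx(-1.8973666, abs=1e-6)
        assert p == pytest.approx(0.1075312, abs=1e-6)

    def test_pooled_variant(self):
        stat, p, _ = compare_groups([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], method="pooled")
        assert stat == pytest.approx(-1.8973666, abs=1e-6)
        assert p == pytest.approx(0.0943498, abs=1e-6)

    def test_degenerate_group_is_hard_error(self):
        with pytest.raises(DataError):
            compare_groups([1.0], [1, 2, 3])
        with pytest.raises(DataError):
            compare_groups([2, 2, 2], [3, 3, 3])
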