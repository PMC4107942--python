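"""Group statistics: ROC, t-tests, correlation bands, BH-FDR, group maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (
    brute_force_bh,
    brute_force_operating_point,
    brute_force_roc_area,
)
from sampenmap.core import SampEnParams
from sampenmap.mapping import EntropyMap
from sampenmap.stats import (
    EntropyThresholdClassifier,
    bh_fdr,
    classify_correlation,
    classify_roc_area,
    pearson_with_age,
    pooled_t_test_from_summary,
    roc_area,
    roc_operating_point,
    two_sample_t_test,
    voxelwise_group_map,
)
from sampenmap.volume import BrainMask


class TestROCArea:
    def test_worked_example(self):
        assert roc_area([3, 4, 5], [1, 2, 3.5]) == pytest.approx(8 / 9)

    def test_perfect_separation(self):
        assert roc_area([10, 11], [1, 2, 3]) == 1.0

    def test_identical_lists_are_chance(self):
        assert roc_area([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=12),
           st.lists(st.floats(-100, 100), min_size=1, max_size=12))
    def test_matches_pair_enumeration(self, young, old):
        assert roc_area(young, old) == pytest.approx(brute_force_roc_area(young, old))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        young, old = rng.normal(1, 1, 15), rng.normal(0, 1, 12)
        base = roc_area(young, old)
        for f in (np.exp, np.tanh, lambda v: v ** 3, lambda v: 5 * v - 2):
            assert roc_area(f(young), f(old)) == pytest.approx(base)


class TestOperatingPoint:
    def test_perfect_separation_scores_100(self):
        res = roc_operating_point([5, 6, 7], [1, 2, 3])
        assert res.accuracy == 100.0 and 3 < res.threshold < 5

    def test_matches_exhaustive_enumeration(self):
        young, old = [2, 3, 4, 5], [1, 2.5, 3.5, 6]
        res = roc_operating_point(young, old)
        thr, sens, spec, acc = brute_force_operating_point(young, old)
        assert (res.threshold, res.sensitivity, res.specificity, res.accuracy) == \
            (thr, sens, spec, acc)

    def test_random_instances_match_enumeration(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            young = rng.normal(1, 1, rng.integers(2, 9))
            old = rng.normal(0, 1, rng.integers(2, 9))
            res = roc_operating_point(young, old)
            thr, sens, spec, acc = brute_force_operating_point(young, old)
            assert res.threshold == pytest.approx(thr)
            assert res.accuracy == pytest.approx(acc)

    def test_label_swap_symmetry(self):
        # Swapping groups: the complementary rule (score < thr => 'younger')
        # at the same threshold swaps sensitivity and specificity.
        young, old = [2.0, 3.0, 4.0], [1.0, 1.5, 2.5]
        res = roc_operating_point(young, old)
        sens_swapped = 100.0 * np.mean(np.asarray(old) < res.threshold)
        spec_swapped = 100.0 * np.mean(np.asarray(young) >= res.threshold)
        assert sens_swapped == res.specificity and spec_swapped == res.sensitivity

    def test_classifier_estimator_api(self):
        X = np.array([2.0, 3.0, 4.0, 1.0, 1.5, 2.5])
        y = np.array(["younger"] * 3 + ["elderly"] * 3)
        clf = EntropyThresholdClassifier().fit(X, y)
        assert set(clf.predict([0.0, 10.0])) == {"elderly", "younger"}
        assert clf.score(X, y) == pytest.approx(clf.accuracy_ / 100.0)


class TestTTests:
    def test_reference_summaries_at_n85(self):
        res = pooled_t_test_from_summary(1.7413, 0.0298, 10, 1.6888, 0.0400, 10)
        assert res.df == 18
        assert round(res.p_value, 3) == 0.004

    def test_reference_summaries_at_n128(self):
        res = pooled_t_test_from_summary(1.6980, 0.0359, 10, 1.6407, 0.0517, 10)
        assert round(res.p_value, 3) == 0.010

    def test_identical_groups(self):
        res = pooled_t_test_from_summary(1.0, 0.1, 8, 1.0, 0.1, 8)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_summary_equals_full_data_route(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1.2, 9)
        full = two_sample_t_test(a, b)
        summ = pooled_t_test_from_summary(a.mean(), a.std(ddof=1), a.size,
                                          b.mean(), b.std(ddof=1), b.size)
        assert full.statistic == pytest.approx(summ.statistic)
        assert full.p_value == pytest.approx(summ.p_value)

    def test_welch_option(self):
        res = pooled_t_test_from_summary(1.0, 0.1, 10, 0.5, 0.5, 5, equal_var=False)
        assert res.df < 13  # Welch-Satterthwaite df below pooled df


class TestPearson:
    def test_perfect_correlation(self):
        ages = [20, 30, 40, 50]
        res = pearson_with_age(ages, ages)
        assert res.r == pytest.approx(1.0) and res.category == "perfect"

    def test_moderate_band_for_reference_value(self):
        assert classify_correlation(-0.602) == "moderate"
        assert classify_correlation(-0.626) == "moderate"

    def test_hand_computed_small_fixture(self):
        v = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0])
        a = np.array([10.0, 20.0, 15.0, 40.0, 30.0, 55.0])
        num = np.sum((v - v.mean()) * (a - a.mean()))
        den = np.sqrt(np.sum((v - v.mean()) ** 2) * np.sum((a - a.mean()) ** 2))
        res = pearson_with_age(v, a)
        assert res.r == pytest.approx(num / den)

    def test_band_boundaries(self):
        assert classify_correlation(0.0) == "zero"
        assert classify_correlation(0.34) == "weak"      # rounds to 0.3
        assert classify_correlation(0.36) == "moderate"  # rounds to 0.4
        assert classify_correlation(-0.97) == "perfect"  # rounds to 1.0
        assert classify_correlation(0.9) == "strong"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_age([1.0, 1.0, 1.0], [20.0, 30.0, 40.0])


class TestBHFDR:
    def test_seven_test_reference_vector_group_differences(self):
        p = [0.004, 0.003, 0.003, 0.003, 0.006, 0.006, 0.010]
        q = np.round(bh_fdr(p), 3)
        np.testing.assert_array_equal(q, [0.007] * 6 + [0.010])

    def test_seven_test_reference_vector_age_correlations(self):
        p = [0.005, 0.003, 0.003, 0.003, 0.005, 0.004, 0.007]
        q = np.round(bh_fdr(p), 3)
        np.testing.assert_array_equal(q, [0.006] * 6 + [0.007])

    def test_equal_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.02] * 5), [0.02] * 5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_matches_textbook_step_up_and_dominates_p(self, p):
        q = bh_fdr(p)
        np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12) and np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestClassifyROCArea:
    @pytest.mark.parametrize("area, band", [
        (0.95, "excellent"), (0.90, "excellent"), (0.85, "good"), (0.80, "good"),
        (0.75, "fair"), (0.65, "poor"), (0.55, "bad"), (0.40, "below chance")])
    def test_bands(self, area, band):
        assert classify_roc_area(area) == band

    def test_bands_are_exhaustive(self):
        for a in np.linspace(0, 1, 201):
            assert classify_roc_area(float(a)) in {
                "excellent", "good", "fair", "poor", "bad", "below chance"}


def _make_map(values, mask):
    reasons = np.where(np.isfinite(values), 0, 2).astype(np.uint8)
    reasons[~mask.include] = 5
    return EntropyMap(values=values, reasons=reasons, mask=mask,
                      params=SampEnParams(), data_length=128)


class TestVoxelwiseGroupMap:
    def test_effect_region_dominates_discoveries(self):
        rng = np.random.default_rng(8)
        shape = (8, 8, 4)
        mask = BrainMask(np.ones(shape, bool))
        effect = np.zeros(shape, bool)
        effect[1:4, 1:4, 1:3] = True
        young = [_make_map(rng.normal(1.7, 0.02, shape), mask) for _ in range(8)]
        old = []
        for _ in range(8):
            v = rng.normal(1.7, 0.02, shape)
            v[effect] -= 0.15
            old.append(_make_map(v, mask))
        res = voxelwise_group_map(young, old)
        discovered = res.q_map < 0.05
        assert discovered[effect].mean() > 0.9
        assert discovered[~effect & mask.include].mean() < 0.1

    def test_null_groups_rarely_discover(self):
        rng = np.random.default_rng(9)
        shape = (10, 10, 4)
        mask = BrainMask(np.ones(shape, bool))
        young = [_make_map(rng.normal(1.7, 0.05, shape), mask) for _ in range(6)]
        old = [_make_map(rng.normal(1.7, 0.05, shape), mask) for _ in range(6)]
        res = voxelwise_group_map(young, old)
        assert np.mean(res.q_map[mask.include] < 0.05) <= 0.05

    def test_single_voxel_reduces_to_t_test(self):
        rng = np.random.default_rng(10)
        mask = BrainMask(np.ones((1, 1, 1), bool))
        ys = rng.normal(1.7, 0.05, 6)
        os_ = rng.normal(1.6, 0.05, 6)
        young = [_make_map(np.full((1, 1, 1), v), mask) for v in ys]
        old = [_make_map(np.full((1, 1, 1), v), mask) for v in os_]
        res = voxelwise_group_map(young, old)
        ref = pooled_t_test_from_summary(ys.mean(), ys.std(ddof=1), 6,
                                         os_.mean(), os_.std(ddof=1), 6)
        assert res.t_map[0, 0, 0] == pytest.approx(ref.statistic)
        assert res.p_map[0, 0, 0] == pytest.approx(ref.p_value)

    def test_undefined_subject_flags_voxel_untested(self):
        rng = np.random.default_rng(11)
        shape = (3, 3, 1)
        mask = BrainMask(np.ones(shape, bool))
        young = [_make_map(rng.normal(1.7, 0.05, shape), mask) for _ in range(3)]
        old = [_make_map(rng.normal(1.6, 0.05, shape), mask) for _ in range(3)]
        young[0].values[1, 1, 0] = np.nan
        young[0].reasons[1, 1, 0] = 2
        res = voxelwise_group_map(young, old)
        assert not res.tested[1, 1, 0] and np.isnan(res.q_map[1, 1, 0])
        assert res.tested.sum() == 8
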