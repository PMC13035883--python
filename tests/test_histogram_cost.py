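"""Binning, expected probabilities, chi-squared, Gini, combined cost."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import biasplit as b
from biasplit.histogram_cost import (
    ObservedCounts,
    cost_breakdown,
)

from conftest import tiny_cohort


class TestBuildGrid:
    def test_equal_width_bins_cover_range(self):
        cohort = tiny_cohort(np.arange(11.0))
        grid = b.build_grid(cohort, 5)
        assert grid.shape == (5,)
        assert grid.edges[0][0] < 0 < 10 < grid.edges[0][-1]
        widths = np.diff(grid.edges[0])
        assert np.allclose(widths, widths[0])

    def test_product_grid_cell_count(self, joint_pool):
        grid = b.build_grid(joint_pool, 20)
        assert grid.n_cells == 400

    def test_constant_dimension_falls_back_to_one_bin(self):
        cohort = tiny_cohort(np.column_stack([np.arange(5.0), np.full(5, 7.0)]),
                             dims=("a", "b"))
        with pytest.warns(RuntimeWarning, match="constant"):
            grid = b.build_grid(cohort, 4)
        assert grid.shape == (4, 1)


class TestExpectedProbabilities:
    def test_two_bins_split_at_mean_are_symmetric(self):
        grid = b.HistogramGrid(edges=(np.array([-4.0, 0.0, 4.0]),))
        target = b.MomentSpec(mean=(0.0,), sd=(1.0,))
        probs = b.expected_probabilities(grid, target).probabilities
        assert probs == pytest.approx([0.5, 0.5])

    def test_one_sigma_cells_match_gaussian_cdf(self):
        # cells (mu-sigma, mu) and (mu, mu+sigma): 0.3413 each before
        # renormalization, exactly one half each after
        grid = b.HistogramGrid(edges=(np.array([-1.0, 0.0, 1.0]),))
        target = b.MomentSpec(mean=(0.0,), sd=(1.0,))
        probs = b.expected_probabilities(grid, target).probabilities
        from scipy.stats import norm
        raw = np.diff(norm.cdf([-1.0, 0.0, 1.0]))
        assert raw == pytest.approx([0.3413, 0.3413], abs=1e-4)
        assert probs == pytest.approx([0.5, 0.5])

    def test_probabilities_sum_to_one(self, joint_pool):
        grid = b.build_grid(joint_pool, 15)
        target = b.MomentSpec(mean=(79.9, 171.6), sd=(18.7, 9.7))
        probs = b.expected_probabilities(grid, target).probabilities
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_correlated_bivariate_rectangles(self, joint_pool):
        grid = b.build_grid(joint_pool, 10)
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        target = b.MomentSpec(mean=(79.9, 171.6), sd=(18.7, 9.7), correlation=corr)
        p_corr = b.expected_probabilities(grid, target).probabilities
        p_ind = b.expected_probabilities(
            grid, b.MomentSpec(mean=(79.9, 171.6), sd=(18.7, 9.7))
        ).probabilities
        assert p_corr.sum() == pytest.approx(1.0, abs=1e-9)
        assert not np.allclose(p_corr, p_ind)  # correlation changes the cells

    def test_target_off_support_is_an_error(self):
        grid = b.HistogramGrid(edges=(np.array([0.0, 1.0]),))
        target = b.MomentSpec(mean=(1e6,), sd=(1.0,))
        with pytest.raises(Exception, match="support|mass"):
            b.expected_probabilities(grid, target)


def _counts(values, grid):
    return ObservedCounts(counts=np.asarray(values), grid=grid)


class TestChiSquared:
    grid2 = b.HistogramGrid(edges=(np.array([0.0, 1.0, 2.0]),))
    grid4 = b.HistogramGrid(edges=(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0])))

    def test_observed_equals_expected_gives_zero(self):
        expected = b.ExpectedProbabilities(probabilities=[0.5, 0.5], grid=self.grid2)
        assert b.chi_squared(_counts([5, 5], self.grid2), expected) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_one_dimensional_value(self):
        # O=(10,0), E=(5,5): 25/5 + 25/5 = 10
        expected = b.ExpectedProbabilities(probabilities=[0.5, 0.5], grid=self.grid2)
        assert b.chi_squared(_counts([10, 0], self.grid2), expected) == pytest.approx(10.0, abs=1e-12)

    def test_hand_computed_two_dimensional_value(self):
        # O=(4,0,0,0), uniform E=1 per cell: 9+1+1+1 = 12
        expected = b.ExpectedProbabilities(probabilities=[0.25] * 4, grid=self.grid4)
        assert b.chi_squared(_counts([4, 0, 0, 0], self.grid4), expected) == pytest.approx(12.0, abs=1e-12)

    def test_empty_group_distance_is_zero(self):
        expected = b.ExpectedProbabilities(probabilities=[0.5, 0.5], grid=self.grid2)
        assert b.chi_squared(_counts([0, 0], self.grid2), expected) == 0.0

    def test_out_of_support_sample_penalized_not_infinite(self):
        expected = b.ExpectedProbabilities(probabilities=[1.0, 0.0], grid=self.grid2)
        value = b.chi_squared(_counts([3, 2], self.grid2), expected)
        assert np.isfinite(value) and value >= 2e6

    @given(st.lists(st.integers(0, 50), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_under_cell_reordering(self, counts):
        grid3 = b.HistogramGrid(edges=(np.array([0.0, 1.0, 2.0, 3.0]),))
        probs = np.array([0.2, 0.3, 0.5])
        perm = [2, 0, 1]
        a = b.chi_squared(
            _counts(counts, grid3),
            b.ExpectedProbabilities(probabilities=probs, grid=grid3),
        )
        c = b.chi_squared(
            _counts([counts[i] for i in perm], grid3),
            b.ExpectedProbabilities(probabilities=probs[perm], grid=grid3),
        )
        assert a == pytest.approx(c, rel=1e-12, abs=1e-12)


class TestGini:
    @pytest.mark.parametrize(
        "sizes,value",
        [
            ((500, 500), 0.0),
            ((1, 3), 0.5),
            ((1, 2, 3), 1.0 / 3.0),
            ((7, 0), 1.0),
        ],
    )
    def test_hand_computed_values(self, sizes, value):
        assert b.gini(sizes) == pytest.approx(value, abs=1e-12)

    def test_all_zero_sizes_rejected(self):
        with pytest.raises(ValueError):
            b.gini((0, 0))

    @given(
        st.lists(st.integers(0, 100), min_size=2, max_size=6).filter(lambda s: sum(s) > 0),
        st.integers(1, 20),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_invariance(self, sizes, c):
        assert b.gini([c * s for s in sizes]) == pytest.approx(b.gini(sizes), abs=1e-9)


class TestTotalCost:
    def test_hand_computed_combined_cost(self):
        # chi2=(4,6), sizes=(1,3): Gini=0.5 -> 10 / 0.25 = 40
        assert b.total_cost([4.0, 6.0], [1, 3]) == pytest.approx(40.0, abs=1e-12)

    def test_equal_sizes_reduce_to_chi2_sum(self):
        assert b.total_cost([4.0, 6.0], [10, 10]) == pytest.approx(10.0, abs=1e-12)

    def test_total_collapse_yields_infinite_sentinel(self):
        assert b.total_cost([0.0, 123.0], [7, 0]) == np.inf

    def test_negative_chi2_rejected(self):
        with pytest.raises(ValueError):
            b.total_cost([-1.0, 0.0], [1, 1])

    def test_balance_improvement_lowers_cost_at_fixed_chi2(self):
        chi2s = [3.0, 5.0]
        costs = [b.total_cost(chi2s, s) for s in [(1, 9), (3, 7), (5, 5)]]
        assert costs[0] > costs[1] > costs[2]


class TestBruteForceOracle:
    """Direct formula evaluation on tiny grids/groups matches the module."""

    @given(
        st.lists(st.integers(0, 6), min_size=4, max_size=4),
        st.lists(st.integers(0, 6), min_size=4, max_size=4),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_chi2_gini_cost_match_direct_evaluation(self, c0, c1):
        if sum(c0) + sum(c1) == 0:
            return
        grid = b.HistogramGrid(
            edges=(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))
        )
        probs = np.array([0.1, 0.2, 0.3, 0.4])
        expected = b.ExpectedProbabilities(probabilities=probs, grid=grid)

        def direct_chi2(counts):
            n = sum(counts)
            if n == 0:
                return 0.0
            return sum((o - n * p) ** 2 / (n * p) for o, p in zip(counts, probs))

        sizes = [sum(c0), sum(c1)]
        chi2s = [direct_chi2(c0), direct_chi2(c1)]
        m = 2
        diff = sum(abs(a - b_) for a in sizes for b_ in sizes)
        gini_direct = diff / (2 * (m - 1) * sum(sizes))
        cost_direct = (
            np.inf if gini_direct == 1.0 else sum(chi2s) / (1 - gini_direct) ** 2
        )

        breakdown = cost_breakdown(
            [_counts(c0, grid), _counts(c1, grid)], [expected, expected]
        )
        assert breakdown.chi2_per_group == pytest.approx(chi2s, abs=1e-12)
        assert breakdown.gini == pytest.approx(gini_direct, abs=1e-12)
        if np.isinf(cost_direct):
            assert breakdown.total_cost == np.inf
        else:
            assert breakdown.total_cost == pytest.approx(cost_direct, rel=1e-12)


class TestSerialization:
    def test_grid_and_probabilities_round_trip(self, joint_pool):
        grid = b.build_grid(joint_pool, 8)
        target = b.MomentSpec(mean=(79.9, 171.6), sd=(18.7, 9.7))
        expected = b.expected_probabilities(grid, target)
        restored = b.ExpectedProbabilities.from_json(expected.to_json())
        np.testing.assert_allclose(restored.probabilities, expected.probabilities)
        for e1, e2 in zip(restored.grid.edges, grid.edges):
            np.testing.assert_allclose(e1, e2)
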