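"""Greedy multi-restart sampler and baseline splitters."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import biasplit as b
from biasplit.histogram_cost import ObservedCounts, cost_breakdown, expected_probabilities
from biasplit.sampler import greedy_pass

from conftest import GLOBAL_WEIGHT, shifted_targets, tiny_cohort


def _unit_targets(mu0, mu1):
    return [b.MomentSpec(mean=(mu0,), sd=(1.0,)), b.MomentSpec(mean=(mu1,), sd=(1.0,))]


class TestGreedyPass:
    def test_two_samples_at_the_target_means_sort_themselves(self):
        cohort = tiny_cohort([0.0, 10.0])
        targets = _unit_targets(0.0, 10.0)
        grid = b.HistogramGrid(edges=(np.linspace(-3, 13, 9),))
        assignment, breakdown = greedy_pass(cohort, targets, grid, [0, 1])
        assert assignment.group_of == {"p0": 0, "p1": 1}
        # swapped placement must cost strictly more
        expected = [expected_probabilities(grid, t) for t in targets]
        swapped = cost_breakdown(
            [
                ObservedCounts.from_labels(cohort.labels[[1]], grid),
                ObservedCounts.from_labels(cohort.labels[[0]], grid),
            ],
            expected,
        )
        assert breakdown.total_cost < swapped.total_cost

    def test_identical_targets_force_near_equal_sizes(self):
        rng = np.random.default_rng(0)
        cohort = tiny_cohort(rng.normal(0, 1, size=64))
        targets = _unit_targets(0.0, 0.0)
        grid = b.build_grid(cohort, 8)
        _, breakdown = greedy_pass(cohort, targets, grid, np.arange(64))
        assert breakdown.gini <= 2 / 64

    def test_empty_cohort_returns_zero_cost_sentinel(self):
        cohort = b.Cohort(ids=(), labels=np.empty((0, 1)), dims=("x",))
        grid = b.HistogramGrid(edges=(np.array([0.0, 1.0]),))
        assignment, breakdown = greedy_pass(cohort, _unit_targets(0, 1), grid, [])
        assert assignment.group_of == {} and breakdown.total_cost == 0.0

    def test_stored_cost_matches_recomputation_from_scratch(self, weight_mixture_pool):
        pool, targets = weight_mixture_pool
        grid = b.build_grid(pool, 20)
        perm = np.random.default_rng(5).permutation(pool.n)
        assignment, breakdown = greedy_pass(pool, targets, grid, perm)
        expected = [expected_probabilities(grid, t) for t in targets]
        groups = assignment.groups(pool)
        scratch = cost_breakdown(
            [ObservedCounts.from_labels(pool.labels[idx], grid) for idx in groups],
            expected,
        )
        assert breakdown.total_cost == pytest.approx(scratch.total_cost, abs=1e-9)
        assert breakdown.chi2_per_group == pytest.approx(scratch.chi2_per_group, abs=1e-9)


class TestSample:
    def test_deterministic_given_config(self, weight_mixture_pool):
        pool, targets = weight_mixture_pool
        cfg = b.SamplerConfig(iterations=3, seed=11)
        a1 = b.sample(pool, targets, cfg)
        a2 = b.sample(pool, targets, cfg)
        assert a1.group_of == a2.group_of
        assert a1.provenance["winning_restart"] == a2.provenance["winning_restart"]

    def test_best_of_k_cost_non_increasing(self, weight_mixture_pool):
        pool, targets = weight_mixture_pool
        a30 = b.sample(pool, targets, b.SamplerConfig(iterations=10, seed=4))
        trajectory = a30.provenance["best_cost_trajectory"]
        assert all(b_ <= a_ for a_, b_ in zip(trajectory, trajectory[1:]))
        a1 = b.sample(pool, targets, b.SamplerConfig(iterations=1, seed=4))
        assert (
            a30.provenance["final_cost"]["total_cost"]
            <= a1.provenance["final_cost"]["total_cost"]
        )

    def test_recovers_mixture_components(self, weight_mixture_pool):
        pool, targets = weight_mixture_pool
        assignment = b.sample(pool, targets, b.SamplerConfig(iterations=5, seed=1))
        groups = assignment.groups(pool)
        for g, idx in enumerate(groups):
            achieved = pool.labels[idx, 0].mean()
            assert abs(achieved - targets[g].mean[0]) < 1.0
        sizes = assignment.sizes()
        assert b.gini(sizes) <= 0.05

    def test_partition_property(self, weight_mixture_pool):
        pool, targets = weight_mixture_pool
        assignment = b.sample(pool, targets, b.SamplerConfig(iterations=2, seed=0))
        assert set(assignment.group_of) == set(pool.ids)
        assert sum(assignment.sizes()) == pool.n

    def test_mismatched_target_count_rejected(self, weight_mixture_pool):
        pool, targets = weight_mixture_pool
        with pytest.raises(Exception):
            b.sample(pool, targets[:1] * 3, b.SamplerConfig(n_groups=2, iterations=1, seed=0))


class TestGreedyVersusExhaustive:
    """On tiny instances greedy is bounded by the true optimum and beats the
    median random assignment (it is a heuristic, not an exact optimizer)."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cost_bounds_on_small_pools(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        values = np.concatenate([rng.normal(-2, 1, n // 2), rng.normal(2, 1, n // 2)])
        cohort = tiny_cohort(values)
        targets = _unit_targets(-2.0, 2.0)
        grid = b.build_grid(cohort, 4)
        expected = [expected_probabilities(grid, t) for t in targets]

        def cost_of(mask):
            idx0 = [i for i in range(n) if not mask[i]]
            idx1 = [i for i in range(n) if mask[i]]
            return cost_breakdown(
                [
                    ObservedCounts.from_labels(cohort.labels[idx0], grid),
                    ObservedCounts.from_labels(cohort.labels[idx1], grid),
                ],
                expected,
            ).total_cost

        all_costs = sorted(
            cost_of(mask) for mask in itertools.product([0, 1], repeat=n)
        )
        true_min = all_costs[0]
        median_random = all_costs[len(all_costs) // 2]

        assignment = b.sample(cohort, targets, b.SamplerConfig(iterations=5, seed=seed, bins_per_dim=4))
        greedy_cost = assignment.provenance["final_cost"]["total_cost"]
        assert true_min <= greedy_cost + 1e-12
        assert greedy_cost <= median_random


class TestMedianSplit:
    def test_four_distinct_values(self):
        cohort = tiny_cohort([1.0, 2.0, 3.0, 4.0])
        assignment = b.median_split(cohort, 0)
        groups = assignment.groups(cohort)
        assert sorted(cohort.labels[groups[0], 0]) == [1.0, 2.0]
        assert sorted(cohort.labels[groups[1], 0]) == [3.0, 4.0]

    def test_supports_do_not_overlap(self, rng):
        cohort = tiny_cohort(rng.normal(0, 1, 101))
        assignment = b.median_split(cohort, 0)
        groups = assignment.groups(cohort)
        assert cohort.labels[groups[0], 0].max() < cohort.labels[groups[1], 0].min()

    def test_tied_values_degenerate_with_warning(self):
        cohort = tiny_cohort([5.0] * 6)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assignment = b.median_split(cohort, 0)
        assert 0 in assignment.sizes()

    def test_split_by_dimension_name(self, joint_pool):
        assignment = b.median_split(joint_pool, "height_cm")
        assert assignment.provenance["dim_name"] == "height_cm"
        sizes = assignment.sizes()
        assert abs(sizes[0] - sizes[1]) <= 2


class TestRandomSplit:
    def test_sizes_concentrate_and_moments_match(self):
        cohort = b.generate_cohort(1662, GLOBAL_WEIGHT, seed=0)
        assignment = b.random_split(cohort, 2, seed=3)
        sizes = assignment.sizes()
        assert abs(sizes[0] - sizes[1]) < 4 * np.sqrt(1662)
        groups = assignment.groups(cohort)
        se = 18.7 / np.sqrt(min(len(g) for g in groups))
        for idx in groups:
            assert abs(cohort.labels[idx, 0].mean() - cohort.labels[:, 0].mean()) < 3 * se

    def test_deterministic(self, joint_pool):
        a1 = b.random_split(joint_pool, 3, seed=9)
        a2 = b.random_split(joint_pool, 3, seed=9)
        assert a1.group_of == a2.group_of


@given(st.integers(0, 10_000), st.integers(4, 40))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_every_splitter_partitions_every_cohort(seed, n):
    """No splitter drops or duplicates a sample (all available data is used)."""
    rng = np.random.default_rng(seed)
    cohort = tiny_cohort(rng.normal(80, 15, n))
    targets = shifted_targets(GLOBAL_WEIGHT, [5.0])
    for assignment in (
        b.median_split(cohort, 0),
        b.random_split(cohort, 2, seed=seed),
        b.sample(cohort, targets, b.SamplerConfig(iterations=1, seed=seed, bins_per_dim=5)),
    ):
        assert sorted(assignment.group_of) == sorted(cohort.ids)
        assert sum(assignment.sizes()) == n
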