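"""Cost model, top-k colony performance and efficiency curves."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idlecolony import (
    ActivityAllocation,
    CostParameters,
    EfficiencyMode,
    PerformanceSample,
    colony_cost,
    colony_efficiency,
    colony_performance,
    normalized_efficiency_curve,
    topk_prefix_sums,
)


def make_sample(values) -> PerformanceSample:
    values = np.asarray(values, dtype=float)
    return PerformanceSample(values=values, n=len(values))


class TestColonyCost:
    def test_hand_evaluated_formula(self):
        """cp*N + delta*cp*(k + beta*(N-k)) at cp=100, N=10, k=4,
        delta=2, beta=0.2 gives 1000 + 200*(4 + 1.2) = 2040."""
        params = CostParameters(delta=2.0, beta=0.2, production_cost=100.0)
        alloc = ActivityAllocation(n_active=4, n_total=10)
        assert colony_cost(params, alloc) == pytest.approx(2040.0, abs=0.0)

    def test_zero_delta_leaves_only_production_cost(self):
        for k in (1, 5, 10):
            params = CostParameters(delta=0.0, beta=0.7, production_cost=100.0)
            assert colony_cost(params, ActivityAllocation(k, 10)) == 1000.0

    def test_beta_one_makes_cost_activity_independent(self):
        params = CostParameters(delta=2.0, beta=1.0, production_cost=100.0)
        costs = {colony_cost(params, ActivityAllocation(k, 10)) for k in range(1, 11)}
        assert costs == {3000.0}

    def test_strictly_increasing_in_k_when_saving_possible(self):
        params = CostParameters(delta=1.5, beta=0.3, production_cost=50.0)
        costs = [colony_cost(params, ActivityAllocation(k, 20)) for k in range(1, 21)]
        assert all(b > a for a, b in zip(costs, costs[1:]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(delta=-0.1, beta=0.5),
            dict(delta=1.0, beta=-0.1),
            dict(delta=1.0, beta=1.1),
            dict(delta=1.0, beta=0.5, production_cost=0.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CostParameters(**kwargs)

    def test_inconsistent_allocation_rejected(self):
        with pytest.raises(ValueError):
            ActivityAllocation(n_active=11, n_total=10)
        with pytest.raises(ValueError):
            ActivityAllocation(n_active=0, n_total=10)


class TestColonyPerformance:
    def test_top_two_of_three(self):
        assert colony_performance(make_sample([0.9, 0.5, 0.1]), 2) == pytest.approx(1.4)

    def test_all_active_is_total_sum(self):
        values = np.linspace(0.05, 0.95, 19)
        assert colony_performance(make_sample(values), 19) == pytest.approx(values.sum())

    def test_equal_values_scale_linearly_in_k(self):
        s = make_sample([0.3] * 8)
        for k in range(1, 9):
            assert colony_performance(s, k) == pytest.approx(0.3 * k)

    def test_non_decreasing_in_k(self):
        rng = np.random.default_rng(5)
        s = make_sample(rng.random(40))
        perfs = [colony_performance(s, k) for k in range(1, 41)]
        assert all(b >= a for a, b in zip(perfs, perfs[1:]))

    def test_out_of_range_k_rejected(self):
        s = make_sample([0.1, 0.2])
        for k in (0, 3, -1):
            with pytest.raises(ValueError):
                colony_performance(s, k)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        values=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=12
        ),
        data=st.data(),
    )
    def test_matches_exhaustive_subset_maximum(self, values, data):
        """Activating the k top performers attains the maximum performance
        over every size-k subset (brute-force enumeration, N <= 12)."""
        k = data.draw(st.integers(1, len(values)))
        s = make_sample(values)
        brute = max(
            sum(c) for c in itertools.combinations(values, k)
        )
        assert colony_performance(s, k) == pytest.approx(brute, abs=1e-12)

    def test_allocation_selects_top_indices_with_stable_ties(self):
        s = make_sample([0.5, 0.9, 0.5, 0.1])
        alloc = ActivityAllocation.from_sample(s, 2)
        # performance 0.5 is tied between workers 0 and 2; the lower index wins
        assert list(alloc.active_indices) == [1, 0]
        assert alloc.n_inactive == 2


class TestColonyEfficiency:
    def test_ratio_and_difference_examples(self):
        s = make_sample([1.0, 1.0, 1.0, 1.0])
        params = CostParameters(delta=1.0, beta=1.0, production_cost=1.0)
        assert colony_efficiency(s, 4, params, EfficiencyMode.RATIO) == pytest.approx(0.5)
        assert colony_efficiency(s, 4, params, EfficiencyMode.DIFFERENCE) == pytest.approx(-4.0)

    def test_zero_performance_gives_zero_ratio(self):
        s = make_sample([0.0, 0.0, 0.7])
        params = CostParameters(delta=1.0, beta=0.5, production_cost=10.0)
        # the two zero-performers contribute nothing beyond the best worker
        assert colony_efficiency(s, 3, params) == pytest.approx(
            0.7 / colony_cost(params, ActivityAllocation(3, 3))
        )
        zero = make_sample([0.0, 0.0])
        assert colony_efficiency(zero, 2, params) == 0.0


class TestNormalizedCurve:
    def params(self, **kw):
        kw.setdefault("delta", 2.0)
        kw.setdefault("beta", 0.2)
        kw.setdefault("production_cost", 100.0)
        return CostParameters(**kw)

    def test_self_normalization_is_exact(self):
        rng = np.random.default_rng(0)
        s = make_sample(rng.random(30))
        curve = normalized_efficiency_curve(s, np.arange(1, 31), self.params())
        assert curve.values[-1] == 1.0
        assert curve.normalized

    def test_beta_one_curve_strictly_increasing(self):
        rng = np.random.default_rng(1)
        s = make_sample(rng.uniform(0.01, 1.0, 50))
        curve = normalized_efficiency_curve(
            s, np.arange(1, 51), self.params(beta=1.0)
        )
        assert np.all(np.diff(curve.values) > 0)
        assert np.argmax(curve.values) == 49

    def test_ratio_curve_invariant_to_production_cost_scale(self):
        rng = np.random.default_rng(2)
        s = make_sample(rng.random(40))
        k = np.arange(1, 41)
        a = normalized_efficiency_curve(s, k, self.params(production_cost=100.0))
        b = normalized_efficiency_curve(s, k, self.params(production_cost=0.37))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_difference_mode_with_affordable_costs_normalizes(self):
        """When the all-active difference is positive the curve is divided
        by it and equals 1 at k = n."""
        s = make_sample([0.9, 0.8, 0.7, 0.6])
        params = CostParameters(delta=0.5, beta=0.2, production_cost=0.1)
        curve = normalized_efficiency_curve(
            s, np.arange(1, 5), params, EfficiencyMode.DIFFERENCE
        )
        assert curve.normalized
        assert curve.values[-1] == pytest.approx(1.0)

    def test_difference_mode_negative_reference_returns_raw_curve(self):
        s = make_sample([0.9, 0.8, 0.7, 0.6])
        params = self.params()  # production cost 100 dwarfs performance
        curve = normalized_efficiency_curve(
            s, np.arange(1, 5), params, EfficiencyMode.DIFFERENCE
        )
        assert not curve.normalized
        assert np.all(curve.values < 0)
        # raw difference decreases in k: each activation costs more than it yields
        assert np.all(np.diff(curve.values) < 0)

    @pytest.mark.parametrize(
        "k_grid",
        [np.array([1, 2, 3]), np.array([3, 2, 4]), np.array([0, 4]), np.array([2, 5])],
    )
    def test_bad_k_grids_rejected(self, k_grid):
        s = make_sample([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError):
            normalized_efficiency_curve(s, k_grid, self.params())


def test_prefix_sums_equal_sorted_cumsum():
    rng = np.random.default_rng(9)
    v = rng.random(100)
    prefix = topk_prefix_sums(v)
    expected = np.cumsum(sorted(v, reverse=True))
    np.testing.assert_allclose(prefix, expected, rtol=1e-15)
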