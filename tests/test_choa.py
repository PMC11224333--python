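import numpy as np
import pytest
from hypothesis import given, strategies as st

from chimpfs.chaos import SineChaosState
from chimpfs.choa import (ChimpPopulation, CountingObjective, SearchSpace,
                          aggregate_position, choa_step, compute_f,
                          leader_guided_position, optimize,
                          population_spread, sample_coefficients,
                          select_leaders, stochastic_position_update)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestComputeF:
    def test_start(self):
        assert compute_f(0, 100) == 2.5

    def test_end(self):
        assert compute_f(100, 100) == 0.0

    def test_midpoint(self):
        assert compute_f(50, 100) == 1.25

    def test_strictly_decreasing_and_affine(self):
        values = [compute_f(t, 100) for t in range(101)]
        diffs = np.diff(values)
        assert np.all(diffs < 0)
        np.testing.assert_allclose(diffs, diffs[0])

    @pytest.mark.parametrize("t,t_max", [(-1, 100), (101, 100), (0, 0)])
    def test_domain_errors(self, t, t_max):
        with pytest.raises(ValueError):
            compute_f(t, t_max)


class TestSampleCoefficients:
    def test_ranges(self, rng):
        chaos = SineChaosState.from_rng(rng, (4,))
        for f in (0.0, 1.2, 2.5):
            a, c, m = sample_coefficients(f, rng, chaos)
            assert np.all(np.abs(a) <= f + 1e-12)
            assert np.all((c >= 0) & (c <= 2))
            assert np.all((m >= 0) & (m <= 1))

    def test_f_out_of_range(self, rng):
        chaos = SineChaosState.from_rng(rng, (4,))
        with pytest.raises(ValueError):
            sample_coefficients(3.0, rng, chaos)


class TestSelectLeaders:
    def _pop(self, fitnesses):
        n = len(fitnesses)
        return ChimpPopulation(np.arange(n, dtype=float)[:, None],
                               np.asarray(fitnesses, dtype=float))

    def test_ordering(self):
        leaders = select_leaders(self._pop([3, 1, 2, 4, 5]))
        assert leaders.indices[0] == 1
        np.testing.assert_array_equal(leaders.fitnesses, [1, 2, 3, 4])

    def test_all_equal_tie_by_index(self):
        leaders = select_leaders(self._pop([7.0] * 6))
        np.testing.assert_array_equal(leaders.indices, [0, 1, 2, 3])

    def test_stable_sort_with_partial_ties(self):
        leaders = select_leaders(self._pop([0.9, 0.1, 0.5, 0.5, 0.2]))
        np.testing.assert_array_equal(leaders.indices, [1, 4, 2, 3])

    def test_too_small(self):
        with pytest.raises(ValueError):
            select_leaders(self._pop([1, 2, 3]))


class TestLeaderGuidedPosition:
    def test_zero_step_returns_leader(self):
        leader = np.array([1.0, -2.0])
        out = leader_guided_position(np.array([5.0, 5.0]), leader, 0.0, 1.3,
                                     0.7)
        np.testing.assert_array_equal(out, leader)

    def test_vanishing_distance(self):
        leader = np.array([2.0, 3.0])
        out = leader_guided_position(leader, leader, 1.0, 1.0, 1.0)
        np.testing.assert_array_equal(out, leader)

    def test_hand_arithmetic(self):
        out = leader_guided_position(np.array([1.0, 1.0]),
                                     np.array([2.0, 2.0]), 1.0, 1.0, 0.5)
        np.testing.assert_allclose(out, [0.5, 0.5])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            leader_guided_position(np.zeros(2), np.zeros(3), 1.0, 1.0, 1.0)


class TestAggregatePosition:
    def test_idempotent_mean(self):
        v = np.array([1.0, 2.0])
        np.testing.assert_array_equal(aggregate_position(v, v, v, v), v)

    def test_arithmetic(self):
        vs = [np.full(2, k, dtype=float) for k in range(4)]
        np.testing.assert_allclose(aggregate_position(*vs), [1.5, 1.5])

    def test_permutation_symmetry(self, rng):
        vs = [rng.normal(size=3) for _ in range(4)]
        base = aggregate_position(*vs)
        np.testing.assert_allclose(aggregate_position(vs[2], vs[0], vs[3],
                                                      vs[1]), base)


class TestStochasticPositionUpdate:
    def _setup(self):
        space = SearchSpace.unit(2)
        positions = np.array([[0.1, 0.1], [0.2, 0.2], [0.3, 0.3],
                              [0.4, 0.4]])
        pop = ChimpPopulation(positions, np.arange(4, dtype=float))
        return space, select_leaders(pop)

    def test_aggregate_branch_degenerates_to_common_leader(self):
        space = SearchSpace.unit(2)
        v = np.array([0.6, 0.7])
        pop = ChimpPopulation(np.tile(v, (4, 1)), np.zeros(4))
        leaders = select_leaders(pop)
        coeffs = (np.zeros(4), np.ones(4), np.ones(4))  # a=0
        out = stochastic_position_update(np.array([0.1, 0.9]), leaders,
                                         coeffs, 0.3, np.zeros(2), space)
        np.testing.assert_allclose(out, v)

    def test_chaotic_branch_uses_chaos_values(self):
        space, leaders = self._setup()
        coeffs = (np.zeros(4), np.ones(4), np.ones(4))
        out = stochastic_position_update(np.array([0.1, 0.1]), leaders,
                                         coeffs, 0.7, np.array([1.0, 0.25]),
                                         space)
        np.testing.assert_allclose(out, [1.0, 0.25])

    def test_branch_split_at_half(self):
        space, leaders = self._setup()
        coeffs = (np.zeros(4), np.ones(4), np.ones(4))
        x = np.array([0.9, 0.9])
        chaos_vals = np.array([0.5, 0.5])
        below = stochastic_position_update(x, leaders, coeffs, 0.49,
                                           chaos_vals, space)
        at = stochastic_position_update(x, leaders, coeffs, 0.50,
                                        chaos_vals, space)
        assert not np.allclose(below, at)
        np.testing.assert_allclose(at, chaos_vals)

    def test_u_out_of_range(self):
        space, leaders = self._setup()
        with pytest.raises(ValueError):
            stochastic_position_update(np.zeros(2), leaders,
                                       (np.zeros(4), np.ones(4),
                                        np.ones(4)), 1.5, np.zeros(2), space)


class TestChoaStep:
    def _run_one_step(self, seed=3):
        rng = np.random.default_rng(seed)
        space = SearchSpace.unit(5)
        positions = space.sample(rng, 6)
        counting = CountingObjective(sphere)
        pop = ChimpPopulation(positions, counting.evaluate_all(positions))
        coef_chaos = SineChaosState.from_rng(rng, (6, 4))
        dim_chaos = SineChaosState.from_rng(rng, (6, 5))
        return choa_step(pop, counting, space, 0, 100, rng, coef_chaos,
                         dim_chaos)

    def test_iteration_incremented_and_bounds_kept(self):
        new = self._run_one_step()
        assert new.iteration == 1
        assert np.all(new.positions >= 0.0) and np.all(new.positions <= 1.0)

    def test_determinism(self):
        a = self._run_one_step(seed=11)
        b = self._run_one_step(seed=11)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.fitnesses, b.fitnesses)

    def test_too_small_population(self):
        rng = np.random.default_rng(0)
        space = SearchSpace.unit(3)
        positions = space.sample(rng, 2)
        pop = ChimpPopulation(positions, np.zeros(2))
        coef = SineChaosState.from_rng(rng, (2, 4))
        dim = SineChaosState.from_rng(rng, (2, 3))
        with pytest.raises(ValueError):
            choa_step(pop, sphere, space, 0, 100, rng, coef, dim)

    def test_non_finite_objective_rejected(self):
        rng = np.random.default_rng(0)
        space = SearchSpace.unit(2)
        positions = space.sample(rng, 4)
        pop = ChimpPopulation(positions, np.zeros(4))
        coef = SineChaosState.from_rng(rng, (4, 4))
        dim = SineChaosState.from_rng(rng, (4, 2))
        with pytest.raises(ValueError, match="non-finite"):
            choa_step(pop, lambda x: float("inf"), space, 0, 100, rng,
                      coef, dim)


class TestOptimize:
    def test_determinism(self):
        space = SearchSpace(np.array([-2.0, -2.0]), np.array([2.0, 2.0]))
        a = optimize(sphere, space, n_individuals=8, t_max=30, seed=5)
        b = optimize(sphere, space, n_individuals=8, t_max=30, seed=5)
        np.testing.assert_array_equal(a.best_position, b.best_position)
        np.testing.assert_array_equal(a.best_curve, b.best_curve)

    def test_curve_contract(self):
        space = SearchSpace.unit(3)
        res = optimize(sphere, space, n_individuals=5, t_max=20, seed=0)
        assert len(res.best_curve) == 21
        assert len(res.diversity_curve) == 21
        assert np.all(np.diff(res.best_curve) <= 0)

    def test_t_max_zero_returns_initial_best(self):
        space = SearchSpace.unit(3)
        res = optimize(sphere, space, n_individuals=5, t_max=0, seed=0)
        assert len(res.best_curve) == 1
        assert res.best_fitness == res.best_curve[0]

    def test_positions_within_bounds(self):
        space = SearchSpace(np.array([-1.0]), np.array([3.0]))
        res = optimize(sphere, space, n_individuals=6, t_max=25, seed=2)
        assert np.all(res.population.positions >= -1.0)
        assert np.all(res.population.positions <= 3.0)

    def test_evals_per_generation(self):
        space = SearchSpace.unit(4)
        res = optimize(sphere, space, n_individuals=7, t_max=10, seed=1)
        np.testing.assert_array_equal(res.evals_per_gen, np.full(10, 7))


class TestPopulationSpread:
    def test_collapsed(self):
        assert population_spread(np.tile([1.0, 2.0], (5, 1))) == 0.0

    def test_two_points(self):
        assert population_spread(np.array([[0.0], [2.0]])) == 1.0

    @given(st.floats(-10, 10))
    def test_translation_invariance(self, shift):
        pts = np.array([[0.0, 1.0], [2.0, -1.0], [0.5, 0.5]])
        assert population_spread(pts + shift) == pytest.approx(
            population_spread(pts))
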