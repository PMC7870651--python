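import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gawcc.candidates import CandidateSolution
from gawcc.ga import (
    GaConfig,
    auto_init_length,
    crossover,
    elitism_select,
    ga_run,
    init_population,
    mutate,
)
from gawcc.scoring import SubsetEvaluator


class TestInitPopulation:
    def test_dedup_shrinks_candidates(self, scripted_rng):
        # first candidate drawn as (4, 4, 9) -> collapses to {4, 9}
        rng = scripted_rng([4, 4, 9, 1, 2, 3])
        pop = init_population(10, GaConfig(pop_size=2, init_length=3), rng)
        assert pop[0].indices == (4, 9)
        assert len(pop[0]) == 2
        assert pop[1].indices == (1, 2, 3)

    def test_single_feature_universe(self):
        cfg = GaConfig(pop_size=5, init_length=3)
        pop = init_population(1, cfg, np.random.default_rng(1))
        assert all(cs.indices == (1,) for cs in pop)

    def test_contract_at_scale(self):
        cfg = GaConfig(pop_size=100, init_length=None)
        pop = init_population(1000, cfg, np.random.default_rng(2))
        assert len(pop) == 100
        for cs in pop:
            cs.validate_against(1000)
            assert 1 <= len(cs) <= auto_init_length(1000)

    def test_auto_init_length_rule(self):
        assert auto_init_length(1) == 1
        assert auto_init_length(4) == 2
        assert auto_init_length(100) == 10
        assert auto_init_length(2) == 2  # max(2, ...) capped at n


class TestMutate:
    def test_forced_replacement(self, scripted_rng):
        cs = CandidateSolution.from_values([2, 5, 9])
        out = mutate(cs, 10, scripted_rng([1, 7]))  # position 2nd, value 7
        assert out.indices == (2, 7, 9)
        assert cs.indices == (2, 5, 9)  # input untouched

    def test_collision_shrinks(self, scripted_rng):
        cs = CandidateSolution.from_values([2, 5, 9])
        out = mutate(cs, 10, scripted_rng([1, 9]))
        assert out.indices == (2, 9)

    def test_singleton(self, scripted_rng):
        out = mutate(CandidateSolution.from_values([3]), 10, scripted_rng([0, 6]))
        assert out.indices == (6,)


class TestCrossover:
    def test_forced_window_swap(self, scripted_rng):
        a = CandidateSolution.from_values([1, 2, 3, 4])
        b = CandidateSolution.from_values([5, 6, 7, 8])
        # L=2, both windows start at position 2 (0-based 1)
        ca, cb = crossover(a, b, scripted_rng([2, 1]))
        assert ca.indices == (1, 4, 6, 7)
        assert cb.indices == (2, 3, 5, 8)

    def test_identical_parents_fixed_point(self, scripted_rng):
        a = CandidateSolution.from_values([2, 4, 6])
        ca, cb = crossover(a, a, scripted_rng([2, 0]))
        assert ca.indices == a.indices
        assert cb.indices == a.indices

    def test_collision_shrink(self, scripted_rng):
        a = CandidateSolution.from_values([1, 2])
        b = CandidateSolution.from_values([2, 9])
        # L=1, swap position 1 of each: a gets 2 -> {2}, b gets 1 -> {1, 9}
        ca, cb = crossover(a, b, scripted_rng([1, 0]))
        assert ca.indices == (2,)
        assert cb.indices == (1, 9)


class TestElitism:
    def test_highest_fitness_kept(self):
        pool = [CandidateSolution.from_values(v) for v in ([1], [2], [3])]
        kept, scores = elitism_select(pool, [0.9, 0.5, 0.7], 2)
        assert [c.indices for c in kept] == [(1,), (3,)]
        assert scores == [0.9, 0.7]

    def test_tie_prefers_shorter(self):
        pool = [
            CandidateSolution.from_values([1, 2, 3]),
            CandidateSolution.from_values([4, 5]),
        ]
        kept, _ = elitism_select(pool, [0.8, 0.8], 1)
        assert kept[0].indices == (4, 5)

    def test_identity_when_out_size_equals_pool(self):
        pool = [CandidateSolution.from_values(v) for v in ([3], [1], [2])]
        kept, _ = elitism_select(pool, [0.1, 0.2, 0.3], 3)
        assert {c.indices for c in kept} == {(1,), (2,), (3,)}

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            elitism_select([CandidateSolution.from_values([1])], [0.5], 2)


class ConstantEvaluator:
    def __init__(self, n_features):
        self.n_features = n_features
        self.n_evals = 0

    def fitness(self, cs):
        self.n_evals += 1
        return 0.5


class TestGaRun:
    def test_stagnation_terminates_after_window_plus_one(self):
        cfg = GaConfig(pop_size=10, stagnation_window=10, seed=0)
        result = ga_run(ConstantEvaluator(20), cfg)
        assert result.generations == cfg.stagnation_window + 1
        assert len(result.trajectory) == cfg.stagnation_window + 1

    def test_trajectory_non_decreasing(self, dict_evaluator):
        cfg = GaConfig(pop_size=20, seed=3)
        result = ga_run(dict_evaluator(30), cfg)
        assert all(a <= b for a, b in zip(result.trajectory, result.trajectory[1:]))

    def test_fixed_seed_reproducible(self, dict_evaluator):
        cfg = GaConfig(pop_size=15, seed=9)
        a = ga_run(dict_evaluator(25), cfg)
        b = ga_run(dict_evaluator(25), cfg)
        assert a.trajectory == b.trajectory
        assert a.population == b.population

    def test_zero_rates_freeze_population(self, dict_evaluator):
        cfg = GaConfig(
            pop_size=10, mutation_rate=0.0, crossover_rate=0.0,
            stagnation_window=3, seed=1,
        )
        result = ga_run(dict_evaluator(15), cfg)
        # no operators -> best constant from generation 1 -> stagnation exit
        assert result.generations == 4
        assert len(set(result.trajectory)) == 1

    def test_reaches_additive_optimum(self, dict_evaluator):
        # candidates never grow, so the optimum must fit within the initial
        # length; exactly two features are profitable here -> optimum {1, 2}
        utilities = [0.3, 0.2, -0.1, -0.2, 0.005, -0.05, 0.002, -0.3]
        ev = dict_evaluator(8, utilities=utilities)
        cfg = GaConfig(pop_size=30, init_length=3, seed=5)
        result = ga_run(ev, cfg)
        assert result.best.indices == (1, 2)
        assert result.best_score == pytest.approx(ev.fitness(ev.exhaustive_best()))

    def test_separable_table_reaches_perfect_fitness(
        self, separable_table, separable_plan
    ):
        # feature 1 alone classifies perfectly; exhaustive scoring of all
        # 31 subsets confirms 1.0 is the maximum, so the GA must reach it
        evaluator = SubsetEvaluator(separable_table, separable_plan)
        best = max(
            evaluator.fitness(CandidateSolution.from_values(sub))
            for r in range(1, 6)
            for sub in itertools.combinations(range(1, 6), r)
        )
        assert best == 1.0
        result = ga_run(evaluator, GaConfig(pop_size=20, seed=2))
        assert result.best_score == 1.0

    def test_every_generation_satisfies_invariants(self, dict_evaluator):
        cfg = GaConfig(pop_size=12, seed=7)
        result = ga_run(dict_evaluator(40), cfg)
        for cs in result.population:
            cs.validate_against(40)


@settings(max_examples=300, deadline=None)
@given(
    data=st.data(),
    n=st.integers(min_value=2, max_value=40),
)
def test_operator_outputs_always_valid(data, n):
    values = data.draw(
        st.lists(st.integers(min_value=1, max_value=n), min_size=1, max_size=10)
    )
    cs = CandidateSolution.from_values(values)
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    m = mutate(cs, n, rng)
    m.validate_against(n)
    assert len(m) <= len(cs)
    other = CandidateSolution.from_values(
        data.draw(st.lists(st.integers(min_value=1, max_value=n), min_size=1, max_size=10))
    )
    ca, cb = crossover(cs, other, rng)
    ca.validate_against(n)
    cb.validate_against(n)
    assert len(ca) <= len(cs) and len(cb) <= len(other)
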