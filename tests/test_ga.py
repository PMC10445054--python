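"""Genetic-algorithm mechanics: composition, mutation, adaptation, stopping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from demfit.demography import ParameterSpace, Variable
from demfit.ga import (CachingObjective, Candidate, GAConfig, adapt,
                       composition_counts, crossover, initial_design, mutate,
                       next_generation, optimize)


def make_space(n=4, lo=-5.0, hi=5.0):
    return ParameterSpace([Variable(f"x{i}", "continuous", lo, hi)
                           for i in range(n)])


def sphere(v):
    return -sum(x * x for x in v)


class TestConfig:
    def test_presets_match_published_columns(self):
        d = GAConfig.default()
        assert (d.gen_size, d.n_init_const) == (10, 10)
        assert d.fractions == (0.20, 0.30, 0.30, 0.20)
        n = GAConfig.new_default()
        assert n.fractions == (0.30, 0.20, 0.30, 0.20)
        assert n.mutation_strength == 0.776
        assert n.const_mutation_rate == 1.475

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GAConfig(p_elitism=0.5, p_mutation=0.5, p_crossover=0.5,
                     p_random=0.5)

    def test_stop_iterations_scale_with_gen_size(self):
        assert GAConfig.default().stop_iterations == 100
        assert GAConfig(gen_size=50, n_init_const=10).stop_iterations == 20

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            GAConfig(const_mutation_rate=2.5)


class TestComposition:
    @pytest.mark.parametrize("fractions,gen_size,expected", [
        ((0.30, 0.20, 0.30, 0.20), 10, (3, 2, 3, 2)),
        ((0.40, 0.08, 0.42, 0.10), 50, (20, 4, 21, 5)),
        ((0.20, 0.30, 0.30, 0.20), 10, (2, 3, 3, 2)),
    ])
    def test_largest_remainder_examples(self, fractions, gen_size, expected):
        assert composition_counts(fractions, gen_size) == expected

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=4,
                    max_size=4).filter(lambda f: sum(f) > 0.1),
           st.sampled_from([10, 50, 100]))
    @settings(deadline=None, max_examples=50)
    def test_counts_sum_to_gen_size(self, raw, gen_size):
        total = sum(raw)
        fractions = [f / total for f in raw]
        assert sum(composition_counts(fractions, gen_size)) == gen_size


class TestAdapt:
    def test_one_fifth_rule_arithmetic(self):
        assert adapt(0.273, 1.475, True) == pytest.approx(0.402675)
        assert adapt(0.273, 1.475, False) == \
            pytest.approx(0.273 / 1.475 ** 0.25)

    def test_identity_constant(self):
        assert adapt(0.4, 1.0, True) == 0.4
        assert adapt(0.4, 1.0, False) == 0.4

    def test_clipped_to_unit_interval(self):
        assert adapt(0.9, 2.0, True) == 1.0
        assert adapt(2e-4, 2.0, False) >= 1e-4


class TestMutate:
    def test_certain_mutation_changes_every_free_variable(self, rng):
        space = make_space(5, 1.0, 2.0)
        c = Candidate([1.5] * 5)
        out = mutate(c, space, strength=1.0, rate=0.5, rng=rng)
        assert all(a != b for a, b in zip(out.values, c.values))

    def test_fixed_variables_never_change(self, rng):
        space = ParameterSpace([
            Variable("a", "continuous", 0.0, 10.0),
            Variable("b", "continuous", 0.0, 10.0, fixed_value=3.0),
        ])
        for _ in range(20):
            out = mutate(Candidate([5.0, 3.0]), space, 1.0, 0.5, rng)
            assert out.values[1] == 3.0

    def test_output_within_bounds(self, rng):
        space = make_space(3, 0.5, 2.0)
        for _ in range(50):
            out = mutate(Candidate([1.9, 0.6, 1.0]), space, 1.0, 2.0, rng)
            for v, var in zip(out.values, space):
                assert var.lower <= v <= var.upper

    def test_seeded_determinism(self):
        space = make_space(4)
        c = Candidate([1.0, -2.0, 3.0, 0.5])
        a = mutate(c, space, 0.5, 0.3, np.random.default_rng(9))
        b = mutate(c, space, 0.5, 0.3, np.random.default_rng(9))
        assert a.values == b.values

    def test_categorical_resampled_among_others(self, rng):
        space = ParameterSpace([Variable("d", "categorical",
                                         categories=("x", "y", "z"))])
        for _ in range(20):
            out = mutate(Candidate(["x"]), space, 1.0, 0.5, rng)
            assert out.values[0] in ("y", "z")


class TestCrossover:
    def test_identical_parents_identical_child(self, rng):
        p = Candidate([1.0, 2.0, 3.0])
        assert crossover(p, p, rng).values == p.values

    def test_child_values_come_from_parents(self, rng):
        p1, p2 = Candidate([1.0, 2.0, 3.0]), Candidate([4.0, 5.0, 6.0])
        for _ in range(20):
            child = crossover(p1, p2, rng)
            for k, v in enumerate(child.values):
                assert v in (p1.values[k], p2.values[k])

    def test_inherits_from_both_parents_when_different(self, rng):
        p1, p2 = Candidate([1.0, 2.0, 3.0]), Candidate([4.0, 5.0, 6.0])
        for _ in range(50):
            child = crossover(p1, p2, rng)
            assert child.values != p1.values
            assert child.values != p2.values

    def test_seeded_determinism(self):
        p1, p2 = Candidate([1.0, 2.0]), Candidate([3.0, 4.0])
        a = crossover(p1, p2, np.random.default_rng(3))
        b = crossover(p1, p2, np.random.default_rng(3))
        assert a.values == b.values


class TestInitialDesign:
    def test_design_size_and_survivors(self):
        space = make_space()
        counting = CachingObjective(sphere)
        pop = initial_design(space, GAConfig.new_default(),
                             np.random.default_rng(0), counting)
        assert counting.calls == 100          # gen_size x n_init_const
        assert len(pop) == 10
        fitnesses = [c.fitness for c in pop]
        assert fitnesses == sorted(fitnesses, reverse=True)

    def test_seeded_reproducibility(self):
        space = make_space()
        a = initial_design(space, GAConfig.default(),
                           np.random.default_rng(5), CachingObjective(sphere))
        b = initial_design(space, GAConfig.default(),
                           np.random.default_rng(5), CachingObjective(sphere))
        assert [c.values for c in a] == [c.values for c in b]

    def test_all_minus_inf_raises(self):
        space = make_space()
        with pytest.raises(RuntimeError):
            initial_design(space, GAConfig.default(),
                           np.random.default_rng(0),
                           CachingObjective(lambda v: float("-inf")))


class TestNextGeneration:
    def test_elitism_never_decreases_best(self, rng):
        space = make_space()
        counting = CachingObjective(sphere)
        pop = initial_design(space, GAConfig.new_default(), rng, counting)
        best = pop[0].fitness
        for _ in range(5):
            pop = next_generation(pop, space, GAConfig.new_default(), rng,
                                  counting)
            assert pop[0].fitness >= best
            best = pop[0].fitness

    def test_population_size_preserved(self, rng):
        space = make_space()
        counting = CachingObjective(sphere)
        pop = initial_design(space, GAConfig.new_default(), rng, counting)
        out = next_generation(pop, space, GAConfig.new_default(), rng, counting)
        assert len(out) == 10


class TestOptimize:
    def test_constant_objective_stops_after_exact_iterations(self):
        space = make_space(3)
        res = optimize(lambda v: 0.0, space, GAConfig.new_default(), seed=1)
        assert len(res.trace) - 1 == 100
        assert res.termination == "no_improvement"

    def test_eval_budget_respected(self):
        space = make_space(4)
        budget = 200 * 4
        res = optimize(sphere, space,
                       GAConfig.new_default(eval_budget=budget), seed=2)
        assert res.evaluations <= budget
        assert res.termination in ("eval_budget", "no_improvement")

    def test_trace_monotone_nondecreasing(self):
        space = make_space(4)
        res = optimize(sphere, space, GAConfig.new_default(eval_budget=600),
                       seed=3)
        assert all(b >= a for a, b in zip(res.trace, res.trace[1:]))
        assert res.evaluations >= len(res.trace)

    def test_seeded_runs_identical(self):
        space = make_space(4)
        a = optimize(sphere, space, GAConfig.new_default(eval_budget=500), seed=11)
        b = optimize(sphere, space, GAConfig.new_default(eval_budget=500), seed=11)
        assert a.trace == b.trace
        assert a.best.values == b.best.values

    def test_cache_hits_not_recounted(self):
        space = ParameterSpace([Variable("d", "categorical",
                                         categories=("x", "y")),
                                Variable("c", "continuous", 0.0, 1.0)])
        calls = []

        def obj(v):
            calls.append(tuple(v))
            return 1.0 if v[0] == "x" else 0.0

        res = optimize(obj, space, GAConfig.new_default(eval_budget=300), seed=4)
        assert res.evaluations == len(calls)
        assert len(set(calls)) == len(calls)  # every true call is distinct
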