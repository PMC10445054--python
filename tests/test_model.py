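"""Model/Results layer: fitting, polish, ladder, comparison protocol."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from demfit.demography import (CONSTANT, ModelTemplate, ParameterSpace,
                               UnitScaling, Variable, build_space)
from demfit.engine import EngineSettings, expected_afs
from demfit.fixtures import _size_var, _time_var
from demfit.ga import GAConfig
from demfit.model import (DemographicModel, RunStats, compare_configurations,
                          local_polish, lrt_nested, restart_budget, speedup)


def single_pop_fixture():
    """A cheap, fully identifiable one-population expansion model."""
    template = build_space((2,), dynamics=(CONSTANT,))
    truth = {"N_anc": 10_000.0, "dur_pre2": 8_000.0, "N_pre2": 45_000.0}
    values = [truth[n] for n in template.space.names]
    return template, truth, values


@pytest.fixture(scope="module")
def single_pop_fit():
    template, truth, values = single_pop_fixture()
    scaling = UnitScaling(mu=1e-8, L=1e7)
    settings = EngineSettings(rtol=1e-6, corner_padding=0)
    data = expected_afs(template.decode(values), (12,), scaling, settings)
    model = DemographicModel(data, template, scaling, settings)
    result = model.fit(seeds=[1, 2], ga_config=GAConfig.new_default(
        eval_budget=200 * 3))
    return truth, model, result


class TestFitFixedStructure:
    def test_noise_free_recovery_within_five_percent(self, single_pop_fit):
        truth, _, result = single_pop_fit
        for name, value in result.params.items():
            assert value == pytest.approx(truth[name], rel=0.05), name

    def test_same_seeds_reproduce_results(self, single_pop_fit):
        truth, model, first = single_pop_fit
        second = model.fit(seeds=[1, 2], ga_config=GAConfig.new_default(
            eval_budget=200 * 3))
        assert second.best.values == first.best.values
        assert second.loglik == first.loglik

    def test_reported_best_is_max_over_runs(self, single_pop_fit):
        _, _, result = single_pop_fit
        assert result.loglik >= max(r.best.fitness for r in result.runs)

    def test_summary_mentions_loglik_and_parameters(self, single_pop_fit):
        _, _, result = single_pop_fit
        text = result.summary()
        assert "log-likelihood" in text
        for name in result.params:
            assert name in text

    def test_folded_data_handled(self):
        template, truth, values = single_pop_fixture()
        scaling = UnitScaling(mu=1e-8, L=1e7)
        settings = EngineSettings(rtol=1e-6, corner_padding=0)
        from demfit.spectrum import fold
        data = fold(expected_afs(template.decode(values), (12,), scaling,
                                 settings))
        model = DemographicModel(data, template, scaling, settings)
        ll = model.loglik(values)
        assert math.isfinite(ll)

    def test_population_mismatch_rejected(self, rng):
        from demfit.spectrum import AFS
        template = build_space((1, 1))
        with pytest.raises(ValueError):
            DemographicModel(AFS(rng.random(8)), template,
                             UnitScaling(mu=1e-8, L=1e7))


class TestLadder:
    def test_degenerate_ladder_matches_fixed_structure(self):
        template, truth, values = single_pop_fixture()
        scaling = UnitScaling(mu=1e-8, L=1e7)
        settings = EngineSettings(rtol=1e-6, corner_padding=0)
        data = expected_afs(template.decode(values), (10,), scaling, settings)
        cfg = GAConfig.new_default(eval_budget=300)
        model = DemographicModel(data, build_space((2,), dynamics=(CONSTANT,)),
                                 scaling, settings)
        ladder = model.fit_ladder((2,), seeds=[5], ga_config=cfg)
        assert ladder.template.structure.counts == (2,)
        assert math.isfinite(ladder.loglik)

    def test_stage_two_starts_at_stage_one_fitness(self):
        template = build_space((1,), dynamics=(CONSTANT,))
        scaling = UnitScaling(mu=1e-8, L=1e7)
        settings = EngineSettings(rtol=1e-6, corner_padding=0)
        truth_template = build_space((2,), dynamics=(CONSTANT,))
        tvals = {"N_anc": 10_000.0, "dur_pre2": 8_000.0, "N_pre2": 45_000.0}
        data = expected_afs(
            truth_template.decode([tvals[n] for n in truth_template.space.names]),
            (10,), scaling, settings)
        model = DemographicModel(data, template, scaling, settings)
        cfg = GAConfig.new_default(eval_budget=250)
        res = model.fit_ladder((2,), seeds=[3], ga_config=cfg, polish=False)
        stage1, stage2 = res.stages
        ll_end_1 = stage1[1][0].best.fitness
        trace_2 = stage2[1][0].trace
        assert trace_2[0] >= ll_end_1 - 1e-8 * abs(ll_end_1)


class TestLocalPolish:
    def test_reaches_concave_quadratic_maximum(self):
        space = ParameterSpace([Variable(f"x{i}", "continuous", -4.0, 4.0)
                                for i in range(3)])
        target = np.array([0.3, -1.2, 2.0])

        def obj(v):
            return -float(np.sum((np.array(v) - target) ** 2))

        values, fitness, calls = local_polish([1.0, 1.0, 1.0], space, obj)
        assert fitness == pytest.approx(0.0, abs=1e-6)
        assert values == pytest.approx(target, abs=1e-3)
        assert calls > 0

    def test_start_at_optimum_returns_it(self):
        space = ParameterSpace([Variable("x", "continuous", -1.0, 1.0)])
        values, fitness, _ = local_polish([0.0], space,
                                          lambda v: -v[0] ** 2)
        assert fitness == pytest.approx(0.0, abs=1e-12)

    def test_bounds_respected_and_fitness_never_decreases(self):
        space = ParameterSpace([Variable("x", "continuous", 0.0, 1.0)])

        def obj(v):
            return v[0]          # maximum at the upper bound

        values, fitness, _ = local_polish([0.5], space, obj)
        assert 0.0 <= values[0] <= 1.0
        assert fitness >= 0.5

    def test_categoricals_frozen(self):
        space = ParameterSpace([
            Variable("d", "categorical", categories=("a", "b")),
            Variable("x", "continuous", -2.0, 2.0),
        ])
        values, _, _ = local_polish(["a", 1.0], space,
                                    lambda v: -v[1] ** 2)
        assert values[0] == "a"


class TestLRT:
    def test_equal_likelihoods(self):
        out = lrt_nested(-100.0, -100.0, df=2)
        assert out["statistic"] == 0.0
        assert out["p_value"] == pytest.approx(1.0)

    def test_chi2_df2_closed_form(self):
        s = 7.3
        out = lrt_nested(-100.0, -100.0 + s / 2.0, df=2)
        assert out["p_value"] == pytest.approx(math.exp(-s / 2.0))

    def test_clamped_with_warning(self):
        out = lrt_nested(-90.0, -100.0, df=1)
        assert out["statistic"] == 0.0
        assert "warning" in out

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            lrt_nested(-1.0, 0.0, df=0)

    def test_adjustment_flagged_off(self):
        assert lrt_nested(-2.0, -1.0, df=1)["godambe_adjusted"] is False


class TestCompareConfigurations:
    def test_all_three_higher_is_better(self):
        a = RunStats([1.0, 2.0, 3.0, 4.0])
        b = RunStats([2.0, 3.0, 4.0, 5.0])
        assert compare_configurations(a, b) == "better"

    def test_all_three_lower_is_worse(self):
        a = RunStats([2.0, 3.0, 4.0, 5.0])
        b = RunStats([1.0, 2.0, 3.0, 4.0])
        assert compare_configurations(a, b) == "worse"

    def test_identical_samples_incomparable(self):
        a = RunStats([1.0, 2.0, 3.0])
        assert compare_configurations(a, RunStats([1.0, 2.0, 3.0])) == \
            "incomparable"

    def test_mixed_quartiles_incomparable(self):
        a = RunStats([0.0, 10.0, 20.0, 30.0])
        b = RunStats([5.0, 9.0, 19.0, 25.0])   # Q1 higher, median lower
        assert compare_configurations(a, b) == "incomparable"

    @given(st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=4,
                    max_size=40),
           st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=4,
                    max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_antisymmetry(self, xs, ys):
        a, b = RunStats(xs), RunStats(ys)
        ab = compare_configurations(a, b)
        ba = compare_configurations(b, a)
        assert (ab == "better") == (ba == "worse")
        assert (ab == "incomparable") == (ba == "incomparable")


class TestProtocolArithmetic:
    def test_speedup_examples(self):
        assert speedup([900.0], [1000.0]) == pytest.approx(0.10)
        assert speedup([500.0, 700.0], [500.0, 700.0]) == 0.0

    def test_restart_budget_ceiling(self):
        assert restart_budget(1000, 300) == 4
        assert restart_budget(900, 300) == 3

    def test_zero_default_mean_rejected(self):
        with pytest.raises(ValueError):
            speedup([100.0], [0.0])
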