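"""Histories, templates, unit scaling and the structure machinery."""

import math

import numpy as np
import pytest

from demfit.demography import (CONSTANT, EXPONENTIAL, LINEAR,
                               DemographicHistory, Epoch, ModelStructure,
                               SplitEvent, UnitScaling, build_space,
                               increase_structure, scale_units,
                               size_trajectory)
from demfit import fixtures as fx

from conftest import random_history_values


class TestSizeTrajectory:
    def test_exponential_reaches_end_exactly(self):
        ep = Epoch(duration=20_157.0, end_sizes=(37_661.0,),
                   dynamics=(EXPONENTIAL,))
        assert size_trajectory(ep, (7_317.0,), 20_157.0) == (37_661.0,)

    def test_constant_is_end_size_for_all_t(self):
        ep = Epoch(duration=100.0, end_sizes=(8_603_000.0,),
                   dynamics=(CONSTANT,))
        for t in (0.0, 37.0, 100.0):
            assert size_trajectory(ep, (1.0,), t) == (8_603_000.0,)

    def test_exponential_geometric_midpoint(self):
        ep = Epoch(duration=10.0, end_sizes=(16.0,), dynamics=(EXPONENTIAL,))
        assert size_trajectory(ep, (4.0,), 5.0) == pytest.approx((8.0,))

    def test_linear_midpoint(self):
        ep = Epoch(duration=10.0, end_sizes=(16.0,), dynamics=(LINEAR,))
        assert size_trajectory(ep, (4.0,), 5.0) == pytest.approx((10.0,))

    def test_zero_duration_interpolation_is_an_error(self):
        ep = Epoch(duration=0.0, end_sizes=(16.0,), dynamics=(LINEAR,))
        with pytest.raises(ValueError):
            size_trajectory(ep, (4.0,), 0.0)


class TestUnitScaling:
    def test_years_to_generations(self):
        sc = UnitScaling(mu=2.2e-9, L=2_564_692_624.0, generation_time=3.0)
        assert sc.years_to_generations(5_800.0) == pytest.approx(1_933.3333333)

    def test_theta0_recomputed(self):
        sc = UnitScaling(mu=1.5e-8, L=2.87e9)
        assert sc.theta0(17_934.0) == pytest.approx(4 * 17_934 * 1.5e-8 * 2.87e9)

    def test_round_trip_identity(self, split_history, scaling):
        gen = scale_units(split_history, scaling, "to_genetic")
        back = scale_units(gen, scaling, "to_physical")
        assert back.N_anc == pytest.approx(split_history.N_anc, rel=1e-12)
        for a, b in zip(back.epochs(), split_history.epochs()):
            assert a.duration == pytest.approx(b.duration, rel=1e-12)
            assert a.end_sizes == pytest.approx(b.end_sizes, rel=1e-12)
            assert np.asarray(a.migration) == pytest.approx(
                np.asarray(b.migration), rel=1e-12)

    def test_genetic_units_values(self, split_history, scaling):
        gen = scale_units(split_history, scaling, "to_genetic")
        assert gen.N_anc == 1.0
        ep = gen.epochs()[0]
        assert ep.duration == pytest.approx(8_000 / 20_000)
        assert ep.migration[0][1] == pytest.approx(2e-5 * 20_000)

    def test_non_positive_reference_rejected(self, scaling):
        with pytest.raises(ValueError):
            DemographicHistory(N_anc=-5.0, events=[])


class TestBuildSpace:
    def test_structure_2_1_variable_count(self):
        t = build_space((2, 1), migration=False)
        cont = [v for v in t.space if v.kind == "continuous"]
        cat = [v for v in t.space if v.kind == "categorical"]
        assert len(cont) == 7
        assert len(cat) == 3

    def test_symmetric_migration_collapses_pair(self):
        t = build_space((1, 1), migration=True, symmetric=True)
        migs = [v for v in t.space.names if v.startswith("m_")]
        assert migs == ["m_post1"]

    def test_deterministic_ordering(self):
        a = build_space((2, 2), migration=True)
        b = build_space((2, 2), migration=True)
        assert a.space.names == b.space.names

    def test_singleton_dynamics_omitted(self):
        t = build_space((2, 1), migration=False, dynamics=(CONSTANT,))
        assert not any(v.kind == "categorical" for v in t.space)

    def test_mask_inconsistent_with_symmetric_flag(self):
        with pytest.raises(ValueError):
            build_space((1, 1), migration=True, symmetric=True,
                        migration_masks=[[False, True], [False, False]])

    def test_fixed_parameters_excluded_from_dimension(self):
        t = build_space((1, 1), migration=False, fixed={"split_frac": 0.5})
        assert t.space.dimension == len(t.space) - 1


class TestDecodeEncode:
    @pytest.mark.parametrize("make", [
        lambda: fx.drosophila_truth("NOMIG"),
        lambda: fx.drosophila_truth("MIG"),
        lambda: fx.orangutan_truth("MIG"),
        lambda: fx.orangutan_truth("NOMIG"),
    ])
    def test_round_trip_on_truth(self, make):
        f = make()
        values = f.truth_values
        assert f.template.encode(f.template.decode(values)) == values

    def test_round_trip_on_structure_model(self, rng):
        t = build_space((2, 2), migration=True)
        values = random_history_values(t, rng)
        back = t.encode(t.decode(values))
        for a, b in zip(back, values):
            if isinstance(a, str):
                assert a == b
            else:
                assert a == pytest.approx(b, rel=1e-12)

    def test_out_of_bounds_names_variable(self):
        f = fx.orangutan_truth()
        values = list(f.truth_values)
        values[-1] = 1e9  # divergence time above its bound
        with pytest.raises(ValueError, match="dur_post1"):
            f.template.decode(values)

    def test_degenerate_decode_is_standard_neutral(self):
        t = build_space((1,), migration=False)
        h = t.decode([10_000.0])
        assert h.n_pops == 1 and h.events == []

    def test_fraction_split_conserves_size(self):
        t = build_space((1, 1), migration=False, split_mode="fraction")
        vals = {"N_anc": 50_000.0, "split_frac": 0.37, "dur_post1": 1_000.0,
                "N_post1_pop0": 1e4, "N_post1_pop1": 1e4,
                "dyn_post1_pop0": CONSTANT, "dyn_post1_pop1": CONSTANT}
        h = t.decode([vals[n] for n in t.space.names])
        children = h.split().child_start_sizes(50_000.0)
        assert children[0] + children[1] == 50_000.0


class TestIncreaseStructure:
    def test_counts_increment(self):
        t = build_space((1, 1))
        vals = [v.sample(np.random.default_rng(0)) for v in t.space]
        t2, _ = increase_structure(t, vals, 0)
        assert t2.structure.counts == (2, 1)

    def test_exponential_epoch_split_has_geometric_midpoint(self, rng):
        t = build_space((1, 1), migration=False, dynamics=(EXPONENTIAL,))
        names = t.space.names
        vals = dict(zip(names, random_history_values(t, rng)))
        vals["split_frac"] = 0.5
        vals["N_post1_pop0"] = 4.0 * vals["N_anc"] * 0.5
        vals["N_post1_pop1"] = 4.0 * vals["N_anc"] * 0.5
        t2, v2 = increase_structure(t, [vals[n] for n in names], 1)
        d2 = dict(zip(t2.space.names, v2))
        start = vals["N_anc"] * 0.5
        assert d2["N_post1_pop0"] == pytest.approx(
            math.sqrt(start * vals["N_post1_pop0"]))
        assert d2["dur_post1"] == pytest.approx(vals["dur_post1"] / 2)
        assert d2["dur_post2"] == pytest.approx(vals["dur_post1"] / 2)

    def test_migration_rates_inherited_by_both_halves(self, rng):
        t = build_space((1, 1), migration=True)
        vals = random_history_values(t, rng)
        d = dict(zip(t.space.names, vals))
        t2, v2 = increase_structure(t, vals, 1)
        d2 = dict(zip(t2.space.names, v2))
        assert d2["m_post1_01"] == d["m_post1_01"]
        assert d2["m_post2_01"] == d["m_post1_01"]

    def test_invalid_component_rejected(self):
        t = build_space((1,))
        with pytest.raises(ValueError):
            increase_structure(t, [1e4], 1)
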