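"""Generator contracts: determinism, ground-truth algebra, monotonicity."""

import numpy as np
import pytest

import agrishock as ash
from agrishock.synthetic_world import SHOCKABLE_COVARIATES


def _single_cell_world(k_times_x, floor=0.0, gamma=0.0, y_pot=10.0,
                       severity=0.0):
    """Evaluate the response on one cell with a single active input."""
    gt = ash.GeoTransform(0.0, 50.0, 0.5)

    def fld(v):
        return ash.GridField(np.full((1, 1), float(v)), gt)

    params = ash.ResponseParams()
    for name in SHOCKABLE_COVARIATES:
        params.k[name] = 0.0
        params.floor[name] = 0.0 if name == "n_rate" else 1.0 - 1e-12
    params.k["n_rate"] = 1.0
    params.floor["n_rate"] = floor
    params.gamma = gamma
    params.nonmineral_n_equiv = 0.0
    covs = {name: fld(0.0) for name in ash.MODEL_COVARIATES}
    covs["n_rate"] = fld(k_times_x * (1.0 - severity))
    out = ash.true_yield(covs, fld(y_pot), params, fld(1.0))
    return float(out.values[0, 0])


class TestTrueYield:
    def test_half_saturation_worked_example(self):
        # k*x = ln 2 -> factor 1 - 2^-1 = 0.5 -> yield 5.0
        assert _single_cell_world(np.log(2.0)) == pytest.approx(5.0, rel=1e-9)

    def test_shocked_half_saturation(self):
        # 50% shock on k*x = ln 2 -> factor 1 - 2^-0.5 -> yield ~2.929
        expect = 10.0 * (1.0 - 2.0 ** -0.5)
        assert _single_cell_world(np.log(2.0), severity=0.5) == pytest.approx(
            expect, rel=1e-9)

    def test_saturation_limit(self):
        assert _single_cell_world(1e6) == pytest.approx(10.0, rel=1e-9)

    def test_zero_input_floor_behaviour(self):
        assert _single_cell_world(0.0, floor=0.0) == 0.0
        assert _single_cell_world(0.0, floor=0.3) == pytest.approx(3.0)

    def test_negative_parameters_rejected(self):
        params = ash.ResponseParams()
        params.k["n_rate"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            params.validate()


class TestGenerateWorld:
    def test_same_seed_bit_identical(self):
        cfg = ash.WorldConfig(n_years=1, seed=3)
        w1, t1 = ash.generate_world(cfg)
        w2, t2 = ash.generate_world(ash.WorldConfig(n_years=1, seed=3))
        assert np.array_equal(w1.yield_t_ha.values, w2.yield_t_ha.values)
        assert np.array_equal(w1.daily_temp_C, w2.daily_temp_C)
        assert np.array_equal(t1.noise_field.values, t2.noise_field.values)
        for name in ash.MODEL_COVARIATES:
            assert np.array_equal(w1.covariates[name].values,
                                  w2.covariates[name].values)

    def test_different_seed_differs(self):
        w1, _ = ash.generate_world(ash.WorldConfig(n_years=1, seed=3))
        w2, _ = ash.generate_world(ash.WorldConfig(n_years=1, seed=4))
        assert not np.array_equal(w1.yield_t_ha.values, w2.yield_t_ha.values)

    def test_zero_noise_yield_equals_deterministic_response(self):
        w, t = ash.generate_world(ash.WorldConfig(n_years=1, seed=5,
                                                  noise_cv=0.0))
        det = t.deterministic_yield(w.covariates)
        m = w.crop_mask
        np.testing.assert_allclose(w.yield_t_ha.values[m], det.values[m],
                                   rtol=1e-12)

    def test_noise_field_reconstructs_yield_exactly(self, small_world):
        _, world, truth = small_world
        rebuilt = ash.true_yield(world.covariates, truth.potential_yield,
                                 truth.response_params, truth.noise_field)
        m = world.crop_mask
        np.testing.assert_allclose(world.yield_t_ha.values[m],
                                   rebuilt.values[m], rtol=1e-12)

    def test_input_rates_positively_correlated(self, small_world):
        _, world, _ = small_world
        m = world.crop_mask
        n = world.covariates["n_rate"].values[m]
        for other in ("p_rate", "k_rate", "pest_herbicide"):
            r = np.corrcoef(n, world.covariates[other].values[m])[0, 1]
            assert r > 0, f"{other} not positively correlated with n_rate"

    def test_machinery_and_labour_constant_within_country(self, small_world):
        _, world, _ = small_world
        cid = world.country_id.values
        for name in ("machinery_hp_per_1000ha", "labour_per_1000ha"):
            vals = world.covariates[name].values
            for c in np.unique(cid):
                assert np.unique(vals[cid == c]).size == 1

    def test_structural_invariants(self, small_world):
        _, world, _ = small_world
        m = world.crop_mask
        assert (world.yield_t_ha.values[m] > 0).all()
        irr = world.covariates["irrigation_share"].values
        assert irr.min() >= 0 and irr.max() <= 100
        for name in ash.MODEL_COVARIATES:
            assert (world.covariates[name].values >= 0).all(), name
        assert (~m).sum() > 0  # some cells really have no cropland

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="grid too small"):
            ash.generate_world(ash.WorldConfig(grid_rows=10, grid_cols=10,
                                               n_years=1))


class TestTrueCounterfactual:
    def test_severity_zero_is_identity(self, small_world):
        _, world, truth = small_world
        scen = ash.ShockScenario("noop", SHOCKABLE_COVARIATES, 0.0)
        cf = ash.true_counterfactual(world, truth, scen)
        np.testing.assert_array_equal(cf.values[world.crop_mask],
                                      world.yield_t_ha.values[world.crop_mask])

    def test_full_shock_hits_response_floors(self, small_world):
        _, world, truth = small_world
        scen = ash.ShockScenario("wipe", SHOCKABLE_COVARIATES, 1.0)
        cf = ash.true_counterfactual(world, truth, scen)
        m = world.crop_mask
        assert (cf.values[m] > 0).all()          # positive floors keep yield up
        assert (cf.values[m] <= world.yield_t_ha.values[m] + 1e-12).all()

    def test_monotone_in_severity(self, small_world):
        _, world, truth = small_world
        m = world.crop_mask
        prev = world.yield_t_ha.values[m]
        for sev in (0.25, 0.5, 0.75, 1.0):
            cf = ash.true_counterfactual(
                world, truth, ash.ShockScenario("s", SHOCKABLE_COVARIATES, sev))
            cur = cf.values[m]
            assert (cur <= prev + 1e-9).all()
            prev = cur

    def test_monotone_in_each_input(self, small_world):
        # raising any shockable input never decreases the true yield
        _, world, truth = small_world
        m = world.crop_mask
        base = ash.true_yield(world.covariates, truth.potential_yield,
                              truth.response_params, truth.noise_field)
        for name in SHOCKABLE_COVARIATES:
            bumped = dict(world.covariates)
            f = world.covariates[name]
            bumped[name] = f.with_values(f.values * 1.3)
            up = ash.true_yield(bumped, truth.potential_yield,
                                truth.response_params, truth.noise_field)
            assert (up.values[m] >= base.values[m] - 1e-12).all(), name

    def test_bad_severity_rejected(self, small_world):
        _, world, truth = small_world
        with pytest.raises(ValueError):
            ash.ShockScenario("bad", ("n_rate",), 1.5)
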