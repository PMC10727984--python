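"""Raw-layer transforms: pesticide processing, gap filling, unit conversion,
feature-table assembly."""

import numpy as np
import pandas as pd
import pytest

import agrishock as ash
from agrishock.input_processing import PESTICIDE_GROUPS


class TestPesticideMeanEstimate:
    def test_high_equals_low(self, unit_grid):
        f = unit_grid(np.random.default_rng(0).random((4, 4)))
        out = ash.pesticide_mean_estimate(f, f)
        np.testing.assert_array_equal(out.values, f.values)

    def test_elementwise_oracle(self, unit_grid):
        rng = np.random.default_rng(1)
        hi, lo = rng.random((4, 4)) + 1, rng.random((4, 4))
        out = ash.pesticide_mean_estimate(unit_grid(hi), unit_grid(lo))
        np.testing.assert_allclose(out.values, (hi + lo) / 2)

    def test_misaligned_rejected(self, unit_grid):
        a = unit_grid(np.zeros((4, 4)))
        b = ash.GridField(np.zeros((5, 5)), a.transform)
        with pytest.raises(ash.GridAlignmentError):
            ash.pesticide_mean_estimate(a, b)


class TestRescalePesticide:
    def test_constant_field_maps_to_one(self, unit_grid):
        out = ash.rescale_pesticide(unit_grid(np.full((4, 4), 3.7)))
        np.testing.assert_array_equal(out.values, np.ones((4, 4)))

    def test_all_zero_field_maps_to_zero(self, unit_grid):
        out = ash.rescale_pesticide(unit_grid(np.zeros((4, 4))))
        np.testing.assert_array_equal(out.values, np.zeros((4, 4)))

    def test_quantile_worked_example(self, unit_grid):
        # rates 1..40: linear-interpolation 97.5th percentile = 39.025
        rates = np.arange(1.0, 41.0).reshape(5, 8)
        gt = ash.GeoTransform(0.0, 50.0, 0.5)
        out = ash.rescale_pesticide(ash.GridField(rates, gt))
        assert out.values[4, 7] == 1.0                       # capped at 1
        assert out.values[2, 3] == pytest.approx(20.0 / 39.025, rel=1e-12)

    def test_output_bounded(self, unit_grid):
        rng = np.random.default_rng(5)
        out = ash.rescale_pesticide(unit_grid(rng.exponential(2.0, (20, 20))))
        assert out.values.min() >= 0 and out.values.max() <= 1

    def test_idempotent_only_when_max_below_one(self, unit_grid):
        once = ash.rescale_pesticide(
            unit_grid(np.random.default_rng(2).random((6, 6))))
        twice = ash.rescale_pesticide(once)
        # second pass rescales by its own 97.5th percentile (< 1), so values move
        assert not np.allclose(once.values, twice.values)

    def test_negative_rates_rejected(self, unit_grid):
        with pytest.raises(ValueError, match="negative"):
            ash.rescale_pesticide(unit_grid(np.full((4, 4), -1.0)))


class TestGroupPesticides:
    def _twenty_layers(self, unit_grid, seed=0):
        rng = np.random.default_rng(seed)
        layers = {f"pest_{i:02d}": unit_grid(rng.random((4, 4)))
                  for i in range(20)}
        gmap = {name: PESTICIDE_GROUPS[i % 4]
                for i, name in enumerate(layers)}
        return layers, gmap

    def test_single_member_group_passthrough(self, unit_grid):
        f = unit_grid(np.random.default_rng(3).random((4, 4)))
        out = ash.group_pesticides({"only": f}, {"only": "Herbicides"})
        np.testing.assert_array_equal(out["Herbicides"].values, f.values)
        np.testing.assert_array_equal(out["Fungicides"].values,
                                      np.zeros((4, 4)))

    def test_duplicate_layer_doubles(self, unit_grid):
        f = unit_grid(np.random.default_rng(4).random((4, 4)))
        out = ash.group_pesticides({"a": f, "b": f},
                                   {"a": "Others", "b": "Others"})
        np.testing.assert_allclose(out["Others"].values, 2 * f.values)

    def test_twenty_layer_sum_oracle(self, unit_grid):
        layers, gmap = self._twenty_layers(unit_grid)
        out = ash.group_pesticides(layers, gmap)
        for group in PESTICIDE_GROUPS:
            want = sum(layers[n].values for n in layers if gmap[n] == group)
            np.testing.assert_allclose(out[group].values, want)

    def test_unmapped_pesticide_rejected(self, unit_grid):
        f = unit_grid(np.zeros((4, 4)))
        with pytest.raises(KeyError, match="missing"):
            ash.group_pesticides({"x": f}, {})


class TestFillMachinery:
    def test_no_gaps_unchanged(self):
        vals = {0: 10.0, 1: 20.0}
        assert ash.fill_machinery(vals, {0: 0, 1: 0}) == vals

    def test_single_donor_continent(self):
        out = ash.fill_machinery({0: 10.0, 1: None}, {0: 0, 1: 0})
        assert out[1] == 10.0

    def test_continent_mean_oracle(self):
        out = ash.fill_machinery({0: 10.0, 1: 20.0, 2: np.nan},
                                 {0: 0, 1: 0, 2: 0})
        assert out[2] == pytest.approx(15.0)

    def test_fill_uses_own_continent_only(self):
        out = ash.fill_machinery({0: 10.0, 1: 99.0, 2: None},
                                 {0: 0, 1: 1, 2: 0})
        assert out[2] == 10.0

    def test_empty_continent_rejected(self):
        with pytest.raises(ValueError, match="no machinery data"):
            ash.fill_machinery({0: None}, {0: 0})


class TestIrrigationShare:
    def test_fully_irrigated(self, unit_grid):
        out = ash.irrigation_share(unit_grid(np.full((4, 4), 5.0)),
                                   unit_grid(np.full((4, 4), 5.0)))
        np.testing.assert_array_equal(out.values, np.full((4, 4), 100.0))

    def test_zero_area_convention_and_ratio(self, unit_grid):
        irr = unit_grid([[25.0, 0.0], [0.0, 10.0]])
        tot = unit_grid([[100.0, 0.0], [50.0, 40.0]])
        out = ash.irrigation_share(irr, tot)
        np.testing.assert_allclose(out.values,
                                   [[25.0, 0.0], [0.0, 25.0]])

    def test_irrigated_exceeding_total_rejected(self, unit_grid):
        with pytest.raises(ValueError, match="exceeds"):
            ash.irrigation_share(unit_grid(np.full((4, 4), 2.0)),
                                 unit_grid(np.full((4, 4), 1.0)))


class TestSoilToTonnesPerHa:
    def test_uniform_density_conversion(self, unit_grid):
        out = ash.soil_to_t_ha(unit_grid(np.full((4, 4), 100.0)), depth_m=0.3)
        np.testing.assert_allclose(out.values, np.full((4, 4), 30.0))

    def test_block_mean_then_convert(self, unit_grid):
        fine = unit_grid([[10.0, 20.0], [30.0, 40.0]])
        out = ash.soil_to_t_ha(fine, depth_m=0.3, block=2)
        assert out.shape == (1, 1)
        assert out.values[0, 0] == pytest.approx(25.0 * 0.3)
        assert out.transform.cell_size_deg == pytest.approx(1.0)

    def test_non_multiple_block_rejected(self, unit_grid):
        with pytest.raises(ValueError, match="multiple"):
            ash.soil_to_t_ha(unit_grid(np.zeros((5, 5))), block=2)

    def test_zero_density(self, unit_grid):
        out = ash.soil_to_t_ha(unit_grid(np.zeros((4, 4))))
        assert (out.values == 0).all()


class TestBuildFeatureTable:
    def test_rows_partition_cropland(self, small_world, small_features):
        _, world, _ = small_world
        assert len(small_features) == int(world.crop_mask.sum())
        assert small_features["cell"].is_unique

    def test_row_round_trips_to_grid(self, small_world, small_features):
        _, world, _ = small_world
        row = small_features.iloc[123]
        r, c = int(row["row"]), int(row["col"])
        assert row["yield_t_ha"] == world.yield_t_ha.values[r, c]
        for name in ash.MODEL_COVARIATES:
            assert row[name] == world.covariates[name].values[r, c], name

    def test_all_bins_nonempty_on_default_world(self, small_features):
        assert small_features["bin_id"].nunique() == 25

    def test_covariate_columns_complete(self, small_features):
        assert not small_features[list(ash.MODEL_COVARIATES)].isna().any().any()

    def test_missing_covariate_rejected(self, small_world, small_bins):
        _, world, _ = small_world
        broken = ash.CropWorld(**{**world.__dict__})
        bad = world.covariates["n_rate"].copy()
        bad.values = bad.values.copy()
        bad.values[world.crop_mask] = np.nan
        broken.covariates = {**world.covariates, "n_rate": bad}
        with pytest.raises(ValueError, match="n_rate"):
            ash.build_feature_table(broken, small_bins)
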