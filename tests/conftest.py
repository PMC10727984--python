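import logging

import numpy as np
import pandas as pd
import pytest

import agrishock as ash

logging.getLogger("agrishock").setLevel(logging.ERROR)

SMALL_YEARS = 2


@pytest.fixture(scope="session")
def small_world():
    """Default-sized world with a short climate record, shared read-only."""
    cfg = ash.WorldConfig(n_years=SMALL_YEARS, seed=42)
    world, truth = ash.generate_world(cfg)
    return cfg, world, truth


@pytest.fixture(scope="session")
def small_bins(small_world):
    _, world, _ = small_world
    gdd = ash.growing_degree_days(world.daily_temp_C, ash.CropClimateSpec(),
                                  n_years=SMALL_YEARS)
    pann = ash.annual_precipitation(world.daily_precip_mm, n_years=SMALL_YEARS)
    return ash.assign_climate_bins(
        ash.GridField(gdd, world.transform, name="gdd"),
        ash.GridField(pann, world.transform, name="precip"),
        world.crop_mask)


@pytest.fixture(scope="session")
def small_features(small_world, small_bins) -> pd.DataFrame:
    _, world, _ = small_world
    return ash.build_feature_table(world, small_bins)


@pytest.fixture(scope="session")
def small_iterations(small_features):
    """Three quick train/test iterations with a reduced forest."""
    cfg = ash.ModelConfig(n_trees=30, n_iterations=3, seed=42)
    return cfg, ash.run_iterations(small_features, cfg)


@pytest.fixture
def unit_grid():
    """4x4 all-valid grid helper for arithmetic-level tests."""
    gt = ash.GeoTransform(0.0, 50.0, 0.5)

    def make(values, mask=None, name=""):
        return ash.GridField(np.asarray(values, dtype=float), gt,
                             mask=mask, name=name)

    return make
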