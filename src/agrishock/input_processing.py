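"""Transforms from raw input layers to the model feature set.

Covers pesticide high/low averaging, 97.5th-percentile rescaling and group
summation, continent-mean filling of missing country machinery values,
irrigation share, topsoil stock conversion with block aggregation, and the
assembly of per-bin feature tables (one row per cropland cell).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .grids import GridField
from .synthetic_world import CropWorld, MODEL_COVARIATES
from .climate_binning import BinAssignment

__all__ = [
    "PESTICIDE_GROUPS",
    "pesticide_mean_estimate",
    "rescale_pesticide",
    "group_pesticides",
    "fill_machinery",
    "irrigation_share",
    "soil_to_t_ha",
    "build_feature_table",
]

#: The four pesticide classes the model distinguishes.
PESTICIDE_GROUPS = ("Herbicides", "Insecticides", "Fungicides", "Others")

RESCALE_PERCENTILE = 97.5


def pesticide_mean_estimate(high: GridField, low: GridField) -> GridField:
    """Cellwise mean of the high and low application-rate estimates."""
    high.require_aligned(low)
    return high.with_values((high.values + low.values) / 2.0)


def rescale_pesticide(rate: GridField, crop_mask: np.ndarray | None = None) -> GridField:
    """Normalize an application rate to [0, 1] by its 97.5th percentile.

    The percentile is taken over cropland cells (linear interpolation
    between order statistics); rates above it saturate at 1.  A field that
    is zero everywhere maps to zero (its percentile carries no scale).
    """
    mask = rate.mask if crop_mask is None else (rate.mask & np.asarray(crop_mask, bool))
    vals = rate.values[mask]
    if vals.size == 0:
        raise ValueError("no valid cells to compute the rescaling percentile")
    if (vals < 0).any():
        raise ValueError("negative application rates")
    q = float(np.percentile(vals, RESCALE_PERCENTILE, method="linear"))
    if q == 0.0:
        return rate.with_values(np.zeros_like(rate.values, dtype=float))
    return rate.with_values(np.minimum(rate.values / q, 1.0))


def group_pesticides(rescaled: Mapping[str, GridField],
                     group_map: Mapping[str, str]) -> dict[str, GridField]:
    """Sum rescaled pesticide layers within each of the four groups."""
    missing = set(rescaled) - set(group_map)
    if missing:
        raise KeyError(f"pesticides missing from group map: {sorted(missing)}")
    bad = set(group_map.values()) - set(PESTICIDE_GROUPS)
    if bad:
        raise ValueError(f"unknown pesticide groups: {sorted(bad)}")
    out: dict[str, GridField] = {}
    any_field = next(iter(rescaled.values()))
    for group in PESTICIDE_GROUPS:
        total = np.zeros(any_field.shape, dtype=float)
        for name, fld in rescaled.items():
            any_field.require_aligned(fld)
            if group_map[name] == group:
                total += fld.values
        out[group] = any_field.with_values(total, name=f"pest_{group.lower()}")
    return out


def fill_machinery(country_values: Mapping[int, float | None],
                   continent_of: Mapping[int, int]) -> dict[int, float]:
    """Complete a country table by filling gaps with the continent mean.

    Missing entries (None or NaN) receive the unweighted mean of the
    available values in the same continent; a continent with no data at all
    is an error.
    """
    unknown = set(country_values) - set(continent_of)
    if unknown:
        raise KeyError(f"countries without continent membership: {sorted(unknown)}")

    def has_data(v):
        return v is not None and np.isfinite(v)

    cont_means: dict[int, float] = {}
    for cont in set(continent_of[c] for c in country_values):
        vals = [country_values[c] for c in country_values
                if continent_of[c] == cont and has_data(country_values[c])]
        if not vals:
            raise ValueError(f"continent {cont} has no machinery data")
        cont_means[cont] = float(np.mean(vals))
    return {c: float(v) if has_data(v) else cont_means[continent_of[c]]
            for c, v in country_values.items()}


def irrigation_share(irrigated_area: GridField,
                     total_harvested_area: GridField) -> GridField:
    """Share (%) of harvested area under irrigation; 0 where nothing is harvested."""
    irrigated_area.require_aligned(total_harvested_area)
    irr, tot = irrigated_area.values, total_harvested_area.values
    if (irr < 0).any() or (tot < 0).any():
        raise ValueError("negative areas")
    if (irr[tot > 0] > tot[tot > 0] + 1e-9).any():
        raise ValueError("irrigated area exceeds total harvested area")
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(tot > 0, 100.0 * irr / np.where(tot > 0, tot, 1.0), 0.0)
    return irrigated_area.with_values(share, name="irrigation_share")


def soil_to_t_ha(density_hg_m3: GridField, depth_m: float = 0.3,
                 block: int = 1) -> GridField:
    """Topsoil stock (t/ha) from a fine-resolution density layer (hg/m3).

    Stock per hectare over depth d is density * 1e4 m2 * d m * 1e-4 t/hg
    = density * d, so the conversion is multiplication by the depth.  With
    ``block`` > 1, block x block fine cells are mean-aggregated into each
    coarse cell first (fine dimensions must be exact multiples).
    """
    if depth_m <= 0:
        raise ValueError("depth must be positive")
    vals = density_hg_m3.values.astype(float)
    mask = density_hg_m3.mask
    if block > 1:
        r, c = vals.shape
        if r % block or c % block:
            raise ValueError(
                f"grid {vals.shape} is not an integer multiple of block {block}")
        vals = vals.reshape(r // block, block, c // block, block).mean(axis=(1, 3))
        mask = mask.reshape(r // block, block, c // block, block).all(axis=(1, 3))
    gt = density_hg_m3.transform
    from .grids import GeoTransform
    coarse = GeoTransform(gt.lon0, gt.lat0, gt.cell_size_deg * block)
    return GridField(vals * depth_m, coarse, mask, "soil_stock_t_ha")


def build_feature_table(world: CropWorld, bins: BinAssignment) -> pd.DataFrame:
    """One row per cropland cell: cell index, bin id, covariates, yield.

    Rows are in row-major cell order; ``cell`` is the flat index into the
    grid, so any row round-trips to its grid values.  Split the frame on
    ``bin_id`` to obtain the per-bin tables the models are fitted on.
    """
    mask = world.crop_mask
    world.yield_t_ha.require_aligned(bins.bin_id)
    cells = np.flatnonzero(mask.ravel())
    data = {"cell": cells,
            "row": cells // world.yield_t_ha.shape[1],
            "col": cells % world.yield_t_ha.shape[1],
            "bin_id": bins.bin_id.values[mask].astype(int)}
    for name in MODEL_COVARIATES:
        fld = world.covariates[name]
        fld.require_aligned(world.yield_t_ha)
        vals = fld.values[mask].astype(float)
        if not np.isfinite(vals).all():
            raise ValueError(f"covariate {name} missing on cropland cells")
        data[name] = vals
    data["yield_t_ha"] = world.yield_t_ha.values[mask].astype(float)
    return pd.DataFrame(data)
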