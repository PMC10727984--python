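"""NetCDF persistence for worlds, truth records and bin assignments.

All gridded layers travel in a single NetCDF (classic format via the scipy
engine) with the geotransform in global attributes; values, nodata masks
and the transform round-trip bit-exactly.  Tables go to CSV, configs to
YAML, manifests to JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import xarray as xr

from .grids import GeoTransform, GridField, GridAlignmentError
from .synthetic_world import (CropWorld, TruthRecord, ResponseParams,
                              MODEL_COVARIATES)
from .climate_binning import BinAssignment

__all__ = ["write_layers", "read_layers", "write_truth", "read_truth",
           "write_bins", "read_bins"]

_ENGINE = "scipy"


def _grid_attrs(gt: GeoTransform) -> dict:
    return {"lon0": gt.lon0, "lat0": gt.lat0, "cell_size_deg": gt.cell_size_deg}


def _transform_of(ds: xr.Dataset) -> GeoTransform:
    return GeoTransform(float(ds.attrs["lon0"]), float(ds.attrs["lat0"]),
                        float(ds.attrs["cell_size_deg"]))


def _field_var(fld: GridField) -> xr.DataArray:
    return xr.DataArray(fld.values, dims=("row", "col"))


def _read_field(ds: xr.Dataset, name: str, mask: np.ndarray,
                gt: GeoTransform) -> GridField:
    return GridField(np.asarray(ds[name].values), gt, mask, name)


def write_layers(world: CropWorld, path: str | Path,
                 include_climate: bool = True) -> Path:
    """Write every layer of a CropWorld to one NetCDF file."""
    path = Path(path)
    data = {
        "yield_t_ha": _field_var(world.yield_t_ha),
        "harvested_area_ha": _field_var(world.harvested_area_ha),
        "country_id": xr.DataArray(world.country_id.values.astype(np.int32),
                                   dims=("row", "col")),
        "continent_id": xr.DataArray(world.continent_id.values.astype(np.int32),
                                     dims=("row", "col")),
        "crop_mask": xr.DataArray(world.yield_t_ha.mask.astype(np.int8),
                                  dims=("row", "col")),
    }
    for name in MODEL_COVARIATES:
        data[name] = _field_var(world.covariates[name])
    if include_climate:
        data["daily_temp_C"] = xr.DataArray(
            world.daily_temp_C.astype(np.float32), dims=("day", "row", "col"))
        data["daily_precip_mm"] = xr.DataArray(
            world.daily_precip_mm.astype(np.float32), dims=("day", "row", "col"))
    ds = xr.Dataset(data, attrs={**_grid_attrs(world.transform),
                                 "n_years": world.n_years})
    ds.to_netcdf(path, engine=_ENGINE)
    return path


def read_layers(path: str | Path) -> CropWorld:
    """Reconstruct a CropWorld from :func:`write_layers` output."""
    with xr.open_dataset(Path(path), engine=_ENGINE) as ds:
        ds.load()
    gt = _transform_of(ds)
    mask = np.asarray(ds["crop_mask"].values, dtype=bool)
    for name in ("yield_t_ha", "harvested_area_ha", *MODEL_COVARIATES):
        if ds[name].shape != mask.shape:
            raise GridAlignmentError(f"layer {name} does not match the grid")
    covs = {name: _read_field(ds, name, mask, gt) for name in MODEL_COVARIATES}
    has_climate = "daily_temp_C" in ds
    return CropWorld(
        yield_t_ha=_read_field(ds, "yield_t_ha", mask, gt),
        harvested_area_ha=_read_field(ds, "harvested_area_ha", mask, gt),
        covariates=covs,
        country_id=_read_field(ds, "country_id", mask, gt),
        continent_id=_read_field(ds, "continent_id", mask, gt),
        daily_temp_C=np.asarray(ds["daily_temp_C"].values) if has_climate else
        np.zeros((0, *mask.shape), np.float32),
        daily_precip_mm=np.asarray(ds["daily_precip_mm"].values) if has_climate
        else np.zeros((0, *mask.shape), np.float32),
        n_years=int(ds.attrs["n_years"]),
    )


def write_truth(truth: TruthRecord, path: str | Path) -> Path:
    path = Path(path)
    ds = xr.Dataset(
        {"potential_yield": _field_var(truth.potential_yield),
         "noise_field": _field_var(truth.noise_field),
         "mask": xr.DataArray(truth.potential_yield.mask.astype(np.int8),
                              dims=("row", "col"))},
        attrs={**_grid_attrs(truth.potential_yield.transform),
               "response_params": json.dumps(asdict(truth.response_params))})
    ds.to_netcdf(path, engine=_ENGINE)
    return path


def read_truth(path: str | Path) -> TruthRecord:
    with xr.open_dataset(Path(path), engine=_ENGINE) as ds:
        ds.load()
    gt = _transform_of(ds)
    mask = np.asarray(ds["mask"].values, dtype=bool)
    params = ResponseParams(**json.loads(ds.attrs["response_params"]))
    return TruthRecord(
        potential_yield=_read_field(ds, "potential_yield", mask, gt),
        noise_field=_read_field(ds, "noise_field", mask, gt),
        response_params=params)


def write_bins(bins: BinAssignment, path: str | Path) -> Path:
    path = Path(path)
    ds = xr.Dataset(
        {"bin_id": xr.DataArray(bins.bin_id.values.astype(np.int32),
                                dims=("row", "col")),
         "gdd_clim": _field_var(bins.gdd_clim),
         "precip_clim": _field_var(bins.precip_clim),
         "mask": xr.DataArray(bins.bin_id.mask.astype(np.int8),
                              dims=("row", "col")),
         "gdd_edges": xr.DataArray(np.asarray(bins.gdd_edges), dims=("edge",)),
         "precip_edges": xr.DataArray(np.asarray(bins.precip_edges),
                                      dims=("edge",))},
        attrs=_grid_attrs(bins.bin_id.transform))
    ds.to_netcdf(path, engine=_ENGINE)
    return path


def read_bins(path: str | Path) -> BinAssignment:
    with xr.open_dataset(Path(path), engine=_ENGINE) as ds:
        ds.load()
    gt = _transform_of(ds)
    mask = np.asarray(ds["mask"].values, dtype=bool)
    return BinAssignment(
        bin_id=_read_field(ds, "bin_id", mask, gt),
        gdd_edges=np.asarray(ds["gdd_edges"].values),
        precip_edges=np.asarray(ds["precip_edges"].values),
        gdd_clim=_read_field(ds, "gdd_clim", mask, gt),
        precip_clim=_read_field(ds, "precip_clim", mask, gt))
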