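"""Growing-degree-day and precipitation climatologies, and 25-bin stratification.

Cropland is stratified into a 5x5 grid of joint quintiles of the two
climatologies so that yield-input relationships can be learned within
strata of comparable climate.  Quintiles are computed over cropland cells
of the crop in question only, with rank-based assignment (value, then
row-major cell index on ties) so marginal quintile occupancies differ by
at most one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridField

__all__ = [
    "CropClimateSpec",
    "BinAssignment",
    "growing_degree_days",
    "annual_precipitation",
    "assign_climate_bins",
]

N_QUANTILES = 5
N_BINS = N_QUANTILES * N_QUANTILES
DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class CropClimateSpec:
    """Crop-specific degree-day thresholds (deg C).

    Heat accumulates on days warmer than ``base_temp_C``; temperatures above
    ``cutoff_temp_C`` are capped at the cutoff (the crop gains nothing from
    additional heat).  The defaults (8/30) suit a generic temperate cereal;
    they are package defaults, set per crop in any real configuration.
    """

    base_temp_C: float = 8.0
    cutoff_temp_C: float = 30.0
    #: "capped_minus_base" (standard degree-day definition) or
    #: "sum_capped_temp" (sum the capped temperature itself on warm days).
    accumulation: str = "capped_minus_base"

    def __post_init__(self) -> None:
        if self.cutoff_temp_C <= self.base_temp_C:
            raise ValueError("cutoff_temp_C must exceed base_temp_C")
        if self.accumulation not in ("capped_minus_base", "sum_capped_temp"):
            raise ValueError(f"unknown accumulation rule {self.accumulation!r}")


def _annual_mean_of_sums(daily: np.ndarray, n_years: int | None) -> np.ndarray:
    daily = np.asarray(daily)
    if daily.shape[0] == 0:
        raise ValueError("empty daily series")
    if n_years is None:
        if daily.shape[0] % DAYS_PER_YEAR:
            raise ValueError(
                f"series length {daily.shape[0]} is not a whole number of "
                f"{DAYS_PER_YEAR}-day years; pass n_years explicitly")
        n_years = daily.shape[0] // DAYS_PER_YEAR
    if n_years < 1 or daily.shape[0] % n_years:
        raise ValueError("series length must be a multiple of n_years")
    per_year = daily.reshape(n_years, daily.shape[0] // n_years, *daily.shape[1:])
    return per_year.sum(axis=1).mean(axis=0)


def growing_degree_days(daily_temps_C: np.ndarray, spec: CropClimateSpec,
                        n_years: int | None = None) -> np.ndarray:
    """Mean annual growing degree days of a daily temperature record.

    ``daily_temps_C`` is a 1-D series for one location or an (n_days, ...)
    stack; annual sums are averaged over the years.  Days at or below the
    base temperature contribute nothing; on warmer days the contribution is
    min(T, cutoff) - base under the default rule, or min(T, cutoff) under
    the literal ``sum_capped_temp`` rule.
    """
    t = np.asarray(daily_temps_C, dtype=float)
    warm = t > spec.base_temp_C
    capped = np.minimum(t, spec.cutoff_temp_C)
    if spec.accumulation == "capped_minus_base":
        contrib = np.where(warm, capped - spec.base_temp_C, 0.0)
    else:
        contrib = np.where(warm, capped, 0.0)
    return _annual_mean_of_sums(contrib, n_years)


def annual_precipitation(daily_precip_mm: np.ndarray,
                         n_years: int | None = None) -> np.ndarray:
    """Mean annual cumulative precipitation (mm/yr) of a daily record."""
    return _annual_mean_of_sums(np.asarray(daily_precip_mm, dtype=float), n_years)


@dataclass
class BinAssignment:
    """Joint climate-bin membership of every cropland cell.

    ``bin_id`` holds 1..25 on cropland (5*(gdd_quintile-1) + precip_quintile)
    and is masked elsewhere.  ``gdd_edges``/``precip_edges`` are the four
    interior quintile thresholds of each marginal, kept for reporting; the
    assignment itself is rank-based and thus invariant to monotone
    transforms of the climatologies.
    """

    bin_id: GridField
    gdd_edges: np.ndarray
    precip_edges: np.ndarray
    gdd_clim: GridField
    precip_clim: GridField

    def bins(self) -> list[int]:
        ids = np.unique(self.bin_id.values[self.bin_id.mask])
        return [int(b) for b in ids]

    def cells_in_bin(self, b: int) -> np.ndarray:
        """Boolean grid of cells assigned to bin ``b``."""
        return self.bin_id.mask & (self.bin_id.values == b)


def _rank_quintile(values: np.ndarray) -> np.ndarray:
    """Quintile index 0..4 per value; ties broken by position (stable sort)."""
    n = values.size
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * N_QUANTILES) // n


def assign_climate_bins(gdd_clim: GridField, precip_clim: GridField,
                        crop_mask: np.ndarray) -> BinAssignment:
    """Stratify cropland into 25 joint GDD x precipitation quintile bins."""
    gdd_clim.require_aligned(precip_clim)
    crop_mask = np.asarray(crop_mask, dtype=bool)
    n = int(crop_mask.sum())
    if n < N_BINS:
        raise ValueError(f"only {n} cropland cells; need at least {N_BINS}")
    g = gdd_clim.values[crop_mask].astype(float)
    p = precip_clim.values[crop_mask].astype(float)
    if not (np.isfinite(g).all() and np.isfinite(p).all()):
        raise ValueError("non-finite climatology on cropland")
    if np.ptp(g) == 0 or np.ptp(p) == 0:
        raise ValueError("constant climatology: quantile stratification is degenerate")

    gq = _rank_quintile(g)
    pq = _rank_quintile(p)
    bin_flat = N_QUANTILES * gq + pq + 1

    bin_vals = np.zeros(crop_mask.shape, dtype=np.int32)
    bin_vals[crop_mask] = bin_flat
    interior = [20, 40, 60, 80]
    return BinAssignment(
        bin_id=GridField(bin_vals, gdd_clim.transform, crop_mask.copy(), "bin_id"),
        gdd_edges=np.percentile(g, interior),
        precip_edges=np.percentile(p, interior),
        gdd_clim=GridField(gdd_clim.values.copy(), gdd_clim.transform,
                           crop_mask.copy(), "gdd_clim"),
        precip_clim=GridField(precip_clim.values.copy(), precip_clim.transform,
                              crop_mask.copy(), "precip_clim"),
    )
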