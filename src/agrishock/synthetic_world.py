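"""Synthetic gridded agricultural world with known ground truth.

The generator emulates the statistical structure of the global gridded
datasets the analysis operates on: per-crop yield and harvested area,
spatially autocorrelated and mutually correlated input-application rates,
country-level-constant machinery and labour, smooth irrigation and soil
layers, and multi-year daily temperature/precipitation with a latitudinal
gradient and seasonal cycle.  Yields come from a known Mitscherlich-type
saturating response, so counterfactual input reductions have an exact
ground truth against which the learned models can be scored.

The response for one cell is

    Y = Y_pot * prod_i f_i(x_i) * g(soil) * l(labour) * eps

with per-input factors f_i(x) = floor_i + (1 - floor_i)(1 - exp(-k_i x b_i)),
where b_i = 1 + gamma * irrigation_share/100 for the mineral fertilizers
(irrigation boosts fertilizer efficiency) and b_i = 1 otherwise; g and l
are monotone saturating multipliers; eps is multiplicative lognormal noise
with mean 1 and coefficient of variation ``noise_cv``.  Every factor is
nondecreasing in its input, so the truth is monotone in every shockable
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import GeoTransform, GridField

__all__ = [
    "SHOCKABLE_COVARIATES",
    "FROZEN_COVARIATES",
    "MODEL_COVARIATES",
    "ResponseParams",
    "WorldConfig",
    "CropWorld",
    "TruthRecord",
    "generate_world",
    "true_yield",
    "true_counterfactual",
]

#: Covariates a shock scenario may reduce (off-farm, trade-dependent inputs).
SHOCKABLE_COVARIATES = (
    "n_rate",
    "p_rate",
    "k_rate",
    "machinery_hp_per_1000ha",
    "pest_herbicide",
    "pest_insecticide",
    "pest_fungicide",
    "pest_other",
)

#: Covariates held constant in every scenario (locally sourced or structural).
FROZEN_COVARIATES = (
    "nonmineral_fert",
    "labour_per_1000ha",
    "irrigation_share",
    "soil_n_t_ha",
    "soil_p",
    "soil_oc_t_ha",
)

#: Full model feature set, in canonical column order.
MODEL_COVARIATES = (
    "n_rate",
    "p_rate",
    "k_rate",
    "nonmineral_fert",
    "machinery_hp_per_1000ha",
    "labour_per_1000ha",
    "pest_herbicide",
    "pest_insecticide",
    "pest_fungicide",
    "pest_other",
    "irrigation_share",
    "soil_n_t_ha",
    "soil_p",
    "soil_oc_t_ha",
)

_FERTILIZER_INPUTS = ("n_rate", "p_rate", "k_rate")


@dataclass
class ResponseParams:
    """Parameters of the saturating yield response.

    ``k`` are per-input rate constants (per unit of the input); ``floor`` is
    the response factor retained when the input is zero (0 disables the
    floor); ``gamma`` scales the irrigation boost on fertilizer efficiency;
    ``soil_k``/``soil_floor`` shape the monotone soil multiplier, and
    ``labour_k``/``labour_floor`` the labour multiplier.  Defaults put
    typical generated input levels in mid-saturation, so responses are
    visibly nonlinear and shocks bite.
    """

    k: dict = field(default_factory=lambda: {
        "n_rate": 0.012,            # per kg N/ha; typical rates sit mid-curve
        "p_rate": 0.040,            # per kg P/ha
        "k_rate": 0.025,            # per kg K/ha
        "machinery_hp_per_1000ha": 0.008,
        "pest_herbicide": 2.0,      # per unit of rescaled group index
        "pest_insecticide": 2.0,
        "pest_fungicide": 2.0,
        "pest_other": 2.0,
    })
    floor: dict = field(default_factory=lambda: {
        "n_rate": 0.15,
        "p_rate": 0.25,
        "k_rate": 0.30,
        "machinery_hp_per_1000ha": 0.75,
        "pest_herbicide": 0.90,
        "pest_insecticide": 0.92,
        "pest_fungicide": 0.94,
        "pest_other": 0.96,
    })
    gamma: float = 0.3
    nonmineral_n_equiv: float = 0.5  # kg mineral-N equivalent per kg non-mineral
    soil_k: dict = field(default_factory=lambda: {
        "soil_n_t_ha": 0.4, "soil_p": 0.01, "soil_oc_t_ha": 0.02})
    soil_floor: float = 0.90
    labour_k: float = 0.01          # per person/1000 ha
    labour_floor: float = 0.95

    def validate(self) -> None:
        for name, v in {**self.k, **self.soil_k,
                        "gamma": self.gamma, "labour_k": self.labour_k}.items():
            if v < 0:
                raise ValueError(f"negative response parameter {name}={v}")
        for name, v in self.floor.items():
            if not 0 <= v < 1:
                raise ValueError(f"floor {name}={v} outside [0,1)")


@dataclass
class WorldConfig:
    """Configuration of the synthetic world generator."""

    grid_rows: int = 50
    grid_cols: int = 50
    cell_size_deg: float = 0.5
    lat0: float = 62.0              # NW-corner latitude (degrees north)
    lon0: float = -10.0
    n_countries: int = 12
    n_continents: int = 4
    n_years: int = 21
    noise_cv: float = 0.10
    noncrop_fraction: float = 0.05  # share of cells with zero harvested area
    potential_yield_max: float = 12.0   # t/ha at the climatic optimum
    seed: int = 0
    response_params: ResponseParams = field(default_factory=ResponseParams)

    def validate(self) -> None:
        if self.grid_rows * self.grid_cols < 625:
            raise ValueError(
                "grid too small: need grid_rows*grid_cols >= 625 so all 25 "
                "climate bins can be populated")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.noncrop_fraction < 0.5:
            raise ValueError("noncrop_fraction must be in [0, 0.5)")
        if self.n_countries < self.n_continents:
            raise ValueError("need at least one country per continent")
        self.response_params.validate()


@dataclass
class CropWorld:
    """All per-crop layers of one crop on a shared grid."""

    yield_t_ha: GridField
    harvested_area_ha: GridField
    covariates: dict[str, GridField]
    country_id: GridField
    continent_id: GridField
    daily_temp_C: np.ndarray        # (n_years*365, rows, cols)
    daily_precip_mm: np.ndarray
    n_years: int

    @property
    def crop_mask(self) -> np.ndarray:
        return (self.harvested_area_ha.values > 0) & self.harvested_area_ha.mask

    @property
    def transform(self) -> GeoTransform:
        return self.yield_t_ha.transform


@dataclass
class TruthRecord:
    """Ground truth saved by the generator for recovery tests."""

    potential_yield: GridField      # Y_pot * g(soil) * l(labour): noise-free ceiling
    noise_field: GridField          # realized multiplicative eps per cell
    response_params: ResponseParams

    def deterministic_yield(self, covariates: Mapping[str, GridField]) -> GridField:
        ones = self.potential_yield.with_values(
            np.ones_like(self.potential_yield.values))
        return true_yield(covariates, self.potential_yield,
                          self.response_params, ones)


def _saturating(x: np.ndarray, k: float, floor: float,
                boost: np.ndarray | float = 1.0) -> np.ndarray:
    return floor + (1.0 - floor) * (1.0 - np.exp(-k * x * boost))


def true_yield(covariates: Mapping[str, GridField], potential_yield: GridField,
               response_params: ResponseParams, noise_field: GridField) -> GridField:
    """Evaluate the deterministic saturating response times the noise field.

    ``potential_yield`` is the full ceiling including soil and labour
    multipliers (as stored in :class:`TruthRecord`); only the shockable-input
    factors are evaluated here, so re-evaluation under shocked covariates is
    exact.
    """
    p = response_params
    p.validate()
    for name in SHOCKABLE_COVARIATES:
        covariates[name].require_aligned(potential_yield)
    irr = covariates["irrigation_share"].values / 100.0
    fert_boost = 1.0 + p.gamma * irr
    out = potential_yield.values.astype(float).copy()
    for name in SHOCKABLE_COVARIATES:
        x = covariates[name].values.astype(float)
        if name == "n_rate":
            x = x + p.nonmineral_n_equiv * covariates["nonmineral_fert"].values
        boost = fert_boost if name in _FERTILIZER_INPUTS else 1.0
        out = out * _saturating(x, p.k[name], p.floor[name], boost)
    out = out * noise_field.values
    return potential_yield.with_values(out, name="yield_t_ha")


def _soil_labour_multiplier(covariates: Mapping[str, np.ndarray],
                            p: ResponseParams) -> np.ndarray:
    g = np.ones_like(np.asarray(covariates["soil_oc_t_ha"], dtype=float))
    for name, k in p.soil_k.items():
        g = g * _saturating(np.asarray(covariates[name], dtype=float),
                            k, p.soil_floor)
    g = g * _saturating(np.asarray(covariates["labour_per_1000ha"], dtype=float),
                        p.labour_k, p.labour_floor)
    return g


def _smooth_unit(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Smoothed standard-normal field rescaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _country_layout(rows: int, cols: int, n_countries: int,
                    n_continents: int) -> tuple[np.ndarray, np.ndarray]:
    # contiguous rectangular blocks: nr x nc bands, surplus ids clipped
    nr = max(1, int(round(np.sqrt(n_countries))))
    nc = int(np.ceil(n_countries / nr))
    band_r = np.minimum(np.arange(rows) * nr // rows, nr - 1)
    band_c = np.minimum(np.arange(cols) * nc // cols, nc - 1)
    cid = np.minimum(band_r[:, None] * nc + band_c[None, :], n_countries - 1)
    cont = cid * n_continents // n_countries
    return cid.astype(np.int32), cont.astype(np.int32)


def _daily_climate(rng: np.random.Generator, lat: np.ndarray, shape,
                   n_years: int, annual_precip: np.ndarray):
    """Daily temperature and precipitation stacks over ``n_years`` years.

    Temperature: latitudinal mean + fine-scale relief (elevation-like,
    fixed over time) + seasonal cosine (amplitude grows with latitude) +
    day-to-day weather noise.  The relief term interleaves climate strata
    at sub-degree scale, as topography does on real cropland, so climate
    bins end up scattered over many coarse blocks rather than forming one
    contiguous band each.  Precipitation: each year's daily weights are
    exponential draws normalized to that year's annual total, with mild
    year-to-year variation around ``annual_precip``.
    """
    days = 365
    doy = np.arange(days, dtype=np.float32)
    relief = 3.0 * gaussian_filter(rng.standard_normal(shape), 1.0,
                                   mode="nearest")
    t_mean = (30.0 - 0.45 * lat + relief).astype(np.float32)  # (rows, cols)
    amp = (4.0 + 0.15 * lat).astype(np.float32)
    season = -np.cos(2 * np.pi * (doy - 15) / days).astype(np.float32)
    temp = np.empty((n_years * days, *shape), dtype=np.float32)
    precip = np.empty_like(temp)
    for y in range(n_years):
        noise = rng.normal(0.0, 2.0, size=(days, *shape)).astype(np.float32)
        temp[y * days:(y + 1) * days] = (
            t_mean[None] + amp[None] * season[:, None, None] + noise)
        w = rng.exponential(1.0, size=(days, *shape)).astype(np.float32)
        w /= w.sum(axis=0, keepdims=True)
        year_total = annual_precip * rng.lognormal(
            -0.02, 0.2, size=shape).astype(np.float32)
        precip[y * days:(y + 1) * days] = w * year_total[None]
    return temp, precip


def generate_world(config: WorldConfig) -> tuple[CropWorld, TruthRecord]:
    """Generate a reproducible synthetic world and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    gt = GeoTransform(config.lon0, config.lat0, config.cell_size_deg)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    lat, _lon = gt.cell_center(rr, cc)

    # cropland mask: smoothed field thresholded -> spatially coherent gaps
    crop_score = _smooth_unit(rng, shape, sigma=2.0)
    thresh = np.quantile(crop_score, config.noncrop_fraction)
    crop_mask = crop_score > thresh

    # intensification latent drives all purchased inputs -> mutual
    # correlation; regional plus local scales so every coarse block mixes
    # a range of input levels.  Rank-transformed to uniform [0,1] so the
    # spread of input levels is wide in every climate stratum.
    raw = (0.3 * _smooth_unit(rng, shape, sigma=3.0)
           + 0.8 * _smooth_unit(rng, shape, sigma=0.8))
    order = np.argsort(raw.ravel(), kind="stable")
    ranks = np.empty(raw.size); ranks[order] = np.arange(raw.size)
    intens = (ranks / max(raw.size - 1, 1)).reshape(shape)

    def jitter(scale: float, sigma: float = 1.2) -> np.ndarray:
        return np.exp(gaussian_filter(rng.standard_normal(shape), sigma,
                                      mode="nearest") * scale)

    covs: dict[str, np.ndarray] = {}
    covs["n_rate"] = 160.0 * intens * jitter(0.15)
    covs["p_rate"] = 50.0 * intens * jitter(0.15)
    covs["k_rate"] = 80.0 * intens * jitter(0.15)
    covs["nonmineral_fert"] = 40.0 * (1.0 - 0.5 * intens) * jitter(0.5)
    # pesticide use tracks intensification only partly (pest pressure is
    # its own geography), which keeps the groups separable from fertilizers
    pest_pressure = _smooth_unit(rng, shape, sigma=1.5)
    for g in ("pest_herbicide", "pest_insecticide", "pest_fungicide", "pest_other"):
        covs[g] = np.clip(2.5 * (0.45 * intens + 0.55 * pest_pressure)
                          * jitter(0.3), 0.0, 4.0)

    cid, cont = _country_layout(*shape, config.n_countries, config.n_continents)
    dev = rng.normal(0.0, 1.0, size=config.n_countries)     # development latent
    mach = 150.0 * np.exp(0.4 * dev)
    lab = 120.0 * np.exp(-0.5 * dev + 0.3 * rng.normal(size=config.n_countries))
    covs["machinery_hp_per_1000ha"] = mach[cid]
    covs["labour_per_1000ha"] = lab[cid]

    # precipitation climatology: west-east gradient, regional structure,
    # and fine-scale (orographic) variation
    precip_ann = (300.0 + 600.0 * _smooth_unit(rng, shape, sigma=3.0)
                  + 400.0 * _smooth_unit(rng, shape, sigma=1.0)
                  + 6.0 * cc).astype(np.float32)
    # irrigation concentrates where it is dry and intensive
    dryness = 1.0 - (precip_ann - precip_ann.min()) / np.ptp(precip_ann)
    covs["irrigation_share"] = np.clip(
        100.0 * dryness * intens * jitter(0.3), 0.0, 100.0)

    covs["soil_n_t_ha"] = 4.0 * _smooth_unit(rng, shape, 2.5) * jitter(0.3) + 0.5
    covs["soil_p"] = 120.0 * _smooth_unit(rng, shape, 2.5) * jitter(0.3) + 20.0
    covs["soil_oc_t_ha"] = 60.0 * _smooth_unit(rng, shape, 2.5) * jitter(0.3) + 10.0

    temp, precip = _daily_climate(rng, lat, shape, config.n_years, precip_ann)

    # climatic potential: Gaussian response surface in (GDD, annual precip)
    from .climate_binning import CropClimateSpec, growing_degree_days
    gdd = growing_degree_days(temp, CropClimateSpec(), n_years=config.n_years)
    pann = precip.reshape(config.n_years, 365, *shape).sum(axis=1).mean(axis=0)
    y_clim = config.potential_yield_max * (
        0.45 + 0.55 * np.exp(-0.5 * (((gdd - 2600.0) / 2500.0) ** 2
                                     + ((pann - 900.0) / 1100.0) ** 2)))

    p = config.response_params
    y_pot = y_clim * _soil_labour_multiplier(covs, p)

    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
        eps = rng.lognormal(-0.5 * sigma ** 2, sigma, size=shape)
    else:
        eps = np.ones(shape)

    def fld(v, name):
        return GridField(np.asarray(v, dtype=float), gt, crop_mask.copy(), name)

    cov_fields = {k: fld(v, k) for k, v in covs.items()}
    pot_field = fld(y_pot, "potential_yield")
    noise_field = fld(eps, "noise")
    yld = true_yield(cov_fields, pot_field, p, noise_field)
    yld.values[~crop_mask] = 0.0

    area = np.where(crop_mask, 100.0 * jitter(0.6), 0.0)
    world = CropWorld(
        yield_t_ha=yld,
        harvested_area_ha=fld(area, "harvested_area_ha"),
        covariates=cov_fields,
        country_id=GridField(cid, gt, crop_mask.copy(), "country_id"),
        continent_id=GridField(cont, gt, crop_mask.copy(), "continent_id"),
        daily_temp_C=temp,
        daily_precip_mm=precip,
        n_years=config.n_years,
    )
    truth = TruthRecord(pot_field, noise_field, p)
    if int(crop_mask.sum()) < 625:
        raise ValueError(
            f"only {int(crop_mask.sum())} cropland cells generated; "
            "climate bins would be under-populated — enlarge the grid or "
            "lower noncrop_fraction")
    return world, truth


def true_counterfactual(world: CropWorld, truth: TruthRecord,
                        scenario) -> GridField:
    """Ground-truth yield under a shock, noise-matched to the baseline.

    Re-evaluates the generator's response with the scenario's covariates
    multiplied by (1 - severity) and the identical realized noise field;
    severity 0 therefore returns the baseline yield exactly.
    """
    if not 0.0 <= scenario.severity <= 1.0:
        raise ValueError("scenario severity must be in [0, 1]")
    shocked = dict(world.covariates)
    for name in scenario.shocked_covariates:
        f = world.covariates[name]
        shocked[name] = f.with_values(f.values * (1.0 - scenario.severity))
    out = true_yield(shocked, truth.potential_yield, truth.response_params,
                     truth.noise_field)
    out.values[~world.crop_mask] = 0.0
    return out


def config_to_dict(config: WorldConfig) -> dict:
    """YAML-serializable representation of a WorldConfig."""
    return asdict(config)


def config_from_dict(d: dict) -> WorldConfig:
    d = dict(d)
    rp = d.pop("response_params", None)
    cfg = WorldConfig(**d)
    if rp is not None:
        cfg.response_params = ResponseParams(**rp)
    return cfg
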