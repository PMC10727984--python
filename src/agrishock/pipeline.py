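"""End-to-end pipeline: generate -> bin -> preprocess -> train -> shock ->
aggregate -> evaluate, with every stage persisted to an output directory.

Stages can run in one process (:func:`run_pipeline`) or individually from
the CLI; each stage reads its prerequisites from the output directory if
they are not already in memory, so the pipeline is resumable.  A manifest
records the configuration, its hash, the master seed and library versions;
reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import io as ashio
from .grids import GridField
from .synthetic_world import (WorldConfig, CropWorld, TruthRecord,
                              generate_world, config_from_dict)
from .climate_binning import (CropClimateSpec, BinAssignment,
                              growing_degree_days, annual_precipitation,
                              assign_climate_bins)
from .input_processing import build_feature_table
from .yield_models import ModelConfig, IterationResult, run_iterations
from .scenario_engine import (ShockScenario, scenario_catalogue, apply_shock,
                              predict_scenario)
from .aggregation import production, country_change, global_change, bin_impact_extent
from .evaluation import evaluation_report, prediction_cv, weighted_country_r2

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Pipeline", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "agrishock_out"
    world: WorldConfig = field(default_factory=WorldConfig)
    climate: CropClimateSpec = field(default_factory=CropClimateSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    #: scenario names to run; None runs the full catalogue + control
    scenario_names: list[str] | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cfg = cls(out_dir=d.get("out_dir", "agrishock_out"),
                  scenario_names=d.get("scenario_names"))
        if "world" in d:
            cfg.world = config_from_dict(d["world"])
        if "climate" in d:
            cfg.climate = CropClimateSpec(**d["climate"])
        if "model" in d:
            cfg.model = ModelConfig(**d["model"])
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class Pipeline:
    """Stage runner bound to one configuration and output directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.world: CropWorld | None = None
        self.truth: TruthRecord | None = None
        self.bins: BinAssignment | None = None
        self.features: pd.DataFrame | None = None
        self.iterations: list[IterationResult] | None = None
        self.scenario_preds: dict[str, np.ndarray] | None = None  # (iter, row)
        self.scenarios: list[ShockScenario] | None = None

    # ------------------------------------------------------------- stages
    def generate(self) -> None:
        self.world, self.truth = generate_world(self.config.world)
        ashio.write_layers(self.world, self.out / "world.nc")
        ashio.write_truth(self.truth, self.out / "truth.nc")
        with open(self.out / "world_config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.config.world), fh, sort_keys=True)

    def _need_world(self) -> CropWorld:
        if self.world is None:
            self.world = ashio.read_layers(self.out / "world.nc")
        return self.world

    def _need_truth(self) -> TruthRecord:
        if self.truth is None:
            self.truth = ashio.read_truth(self.out / "truth.nc")
        return self.truth

    def bin(self) -> None:
        world = self._need_world()
        gdd = growing_degree_days(world.daily_temp_C, self.config.climate,
                                  n_years=world.n_years)
        pann = annual_precipitation(world.daily_precip_mm, n_years=world.n_years)
        gt = world.transform
        mask = world.crop_mask
        self.bins = assign_climate_bins(
            GridField(gdd, gt, name="gdd_clim"),
            GridField(pann, gt, name="precip_clim"), mask)
        ashio.write_bins(self.bins, self.out / "bins.nc")
        with open(self.out / "bin_edges.json", "w") as fh:
            json.dump({"gdd_edges": list(map(float, self.bins.gdd_edges)),
                       "precip_edges": list(map(float, self.bins.precip_edges))},
                      fh, indent=2)

    def _need_bins(self) -> BinAssignment:
        if self.bins is None:
            self.bins = ashio.read_bins(self.out / "bins.nc")
        return self.bins

    def preprocess(self) -> None:
        self.features = build_feature_table(self._need_world(), self._need_bins())
        self.features.to_csv(self.out / "features.csv", index=False)

    def _need_features(self) -> pd.DataFrame:
        if self.features is None:
            self.features = pd.read_csv(self.out / "features.csv")
        return self.features

    def train(self) -> None:
        self.iterations = run_iterations(self._need_features(), self.config.model)
        joblib.dump(self.iterations, self.out / "models.joblib")
        pd.concat([r.metrics.assign(iteration=r.iteration)
                   for r in self.iterations],
                  ignore_index=True).to_csv(
            self.out / "iteration_metrics.csv", index=False)

    def _need_iterations(self) -> list[IterationResult]:
        if self.iterations is None:
            self.iterations = joblib.load(self.out / "models.joblib")
        return self.iterations

    def _catalogue(self) -> list[ShockScenario]:
        if self.scenarios is None:
            cat = scenario_catalogue()
            names = self.config.scenario_names
            self.scenarios = (cat if names is None
                              else [s for s in cat if s.name in names])
        return self.scenarios

    def shock(self) -> None:
        features = self._need_features()
        iters = self._need_iterations()
        preds: dict[str, np.ndarray] = {}
        for scen in self._catalogue():
            shocked = apply_shock(features, scen)
            preds[scen.name] = np.stack(
                [predict_scenario(r, shocked) for r in iters])
        self.scenario_preds = preds
        baseline = np.stack([r.baseline_pred for r in iters])
        ds = xr.Dataset(
            {"baseline": xr.DataArray(baseline, dims=("iteration", "cell")),
             **{f"scenario__{k}": xr.DataArray(v, dims=("iteration", "cell"))
                for k, v in preds.items()}},
            coords={"cell": self._need_features()["cell"].to_numpy()})
        ds.to_netcdf(self.out / "scenario_yields.nc", engine="scipy")

    def _need_preds(self) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        if self.scenario_preds is None:
            with xr.open_dataset(self.out / "scenario_yields.nc",
                                 engine="scipy") as ds:
                ds.load()
            self.scenario_preds = {
                k.removeprefix("scenario__"): np.asarray(ds[k].values)
                for k in ds.data_vars if k.startswith("scenario__")}
            self._baseline_stack = np.asarray(ds["baseline"].values)
        else:
            self._baseline_stack = np.stack(
                [r.baseline_pred for r in self._need_iterations()])
        return self._baseline_stack, self.scenario_preds

    @staticmethod
    def _nanmean_rows(stack: np.ndarray) -> np.ndarray:
        """Column-wise mean over iterations, NaN where no iteration predicted."""
        out = np.full(stack.shape[1], np.nan)
        ok = np.isfinite(stack).any(axis=0)
        if ok.any():
            out[ok] = np.nanmean(stack[:, ok], axis=0)
        return out

    def _yield_field(self, per_row: np.ndarray) -> GridField:
        world = self._need_world()
        vals = np.full(world.yield_t_ha.shape, np.nan)
        feats = self._need_features()
        vals[feats["row"].to_numpy(), feats["col"].to_numpy()] = per_row
        return GridField(vals, world.transform,
                         world.crop_mask & np.isfinite(vals), "yield_t_ha")

    def aggregate(self) -> None:
        world = self._need_world()
        baseline_stack, preds = self._need_preds()
        base_field = self._yield_field(self._nanmean_rows(baseline_stack))
        base_prod = production(base_field, world.harvested_area_ha)
        cat = {s.name: s for s in self._catalogue()}
        rows, country_rows, extent_frames = [], [], []
        for name, stack in preds.items():
            scen = cat[name]
            scen_field = self._yield_field(self._nanmean_rows(stack))
            scen_prod = production(scen_field, world.harvested_area_ha)
            rows.append({"scenario": name, "severity": scen.severity,
                         "is_control": scen.is_control,
                         "global_change_pct": global_change(base_prod, scen_prod)})
            cc = country_change(base_prod, scen_prod, world.country_id)
            cc.insert(0, "scenario", name)
            country_rows.append(cc)
            if scen.severity == 0.50:
                ext = bin_impact_extent(base_field, scen_field,
                                        self._need_bins(),
                                        world.harvested_area_ha)
                ext.insert(0, "scenario", name)
                extent_frames.append(ext)
        self.global_table = pd.DataFrame(rows).sort_values(
            "scenario", ignore_index=True)
        self.global_table.to_csv(self.out / "global_change.csv", index=False)
        pd.concat(country_rows, ignore_index=True).to_csv(
            self.out / "country_change.csv", index=False)
        if extent_frames:
            pd.concat(extent_frames, ignore_index=True).to_csv(
                self.out / "bin_extent.csv", index=False)

    def evaluate(self) -> None:
        world = self._need_world()
        truth = self._need_truth()
        iters = self._need_iterations()
        report = evaluation_report(self._need_features(), iters)
        report.to_csv(self.out / "evaluation.csv", index=False)
        baseline_stack, _ = self._need_preds()
        cv = prediction_cv(baseline_stack)
        feats = self._need_features()
        # country-level validation against the noise-free truth
        det = truth.deterministic_yield(world.covariates)
        base_mean = self._nanmean_rows(baseline_stack)
        r, c = feats["row"].to_numpy(), feats["col"].to_numpy()
        df = pd.DataFrame({
            "country": world.country_id.values[r, c].astype(int),
            "area": world.harvested_area_ha.values[r, c],
            "modelled": base_mean,
            "reference": det.values[r, c]}).dropna()
        df["mod_prod"] = df["modelled"] * df["area"]
        df["ref_prod"] = df["reference"] * df["area"]
        g = df.groupby("country").sum()
        r2 = weighted_country_r2((g["mod_prod"] / g["area"]).to_numpy(),
                                 (g["ref_prod"] / g["area"]).to_numpy(),
                                 g["mod_prod"].to_numpy())
        summary = {
            "weighted_country_r2": float(r2),
            "median_prediction_cv": float(np.nanmedian(cv)),
            "share_bins_nse_above_0.65": float(
                np.mean(report["nse"] > 0.65)) if len(report) else float("nan"),
            "share_bins_nse_above_0.75": float(
                np.mean(report["nse"] > 0.75)) if len(report) else float("nan"),
        }
        with open(self.out / "evaluation_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        self.eval_report = report
        self.eval_summary = summary
        self.cv_per_cell = cv

    def write_manifest(self) -> None:
        import sklearn
        from . import __version__
        manifest = {
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "seed": self.config.world.seed,
            "model_seed": self.config.model.seed,
            "versions": {"agrishock": __version__,
                         "numpy": np.__version__,
                         "pandas": pd.__version__,
                         "scikit-learn": sklearn.__version__},
        }
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def run_pipeline(config: PipelineConfig) -> Pipeline:
    """Run every stage in order and return the populated Pipeline."""
    pipe = Pipeline(config)
    for stage in ("generate", "bin", "preprocess", "train", "shock",
                  "aggregate", "evaluate"):
        logger.info("stage: %s", stage)
        try:
            getattr(pipe, stage)()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    pipe.write_manifest()
    return pipe
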