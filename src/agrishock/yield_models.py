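"""Per climate-bin random-forest yield models with spatially blocked splits.

Within each climate bin, yield is regressed on the model covariates with a
random forest (defaults: 1000 trees, minimum leaf size 5, 2 candidate split
variables).  To limit spatial-autocorrelation leakage between training and
testing, a coarse block grid (12 x 12 model cells, i.e. one degree over a
5-arcmin grid) is imposed over the map and whole blocks are assigned to
train (75%) or test (25%).  Splitting and fitting are repeated over
independent iterations so prediction variability can be quantified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .synthetic_world import MODEL_COVARIATES

__all__ = ["ModelConfig", "IterationResult", "spatial_block_split",
           "train_bin_model", "run_iterations"]

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    n_trees: int = 1000
    min_leaf_size: int = 5
    n_split_vars: int = 2
    block_size_cells: int = 12
    train_fraction: float = 0.75
    n_iterations: int = 25
    #: bins with fewer training rows than this are skipped with a warning
    min_bin_rows: int = 50
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_split_vars > len(MODEL_COVARIATES):
            raise ValueError("n_split_vars exceeds the number of covariates")
        for name in ("n_trees", "min_leaf_size", "block_size_cells",
                     "n_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class IterationResult:
    """Artifacts of one train/test split and fit over all bins."""

    iteration: int
    models: dict[int, RandomForestRegressor]
    train_mask: np.ndarray          # per feature-table row
    baseline_pred: np.ndarray       # per row; NaN where the bin was skipped
    metrics: pd.DataFrame           # per bin: nse, rmse, n_train, n_test
    skipped_bins: list[int] = field(default_factory=list)


def block_index(rows: np.ndarray, cols: np.ndarray, block_size: int) -> np.ndarray:
    """Flat id of the coarse block containing each cell (NW-anchored grid)."""
    br = np.asarray(rows) // block_size
    bc = np.asarray(cols) // block_size
    return br * (int(np.max(bc, initial=0)) + 1) + bc


def spatial_block_split(cells: pd.DataFrame, config: ModelConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Boolean train mask over the rows of ``cells`` (needs row/col columns).

    Whole blocks go to one side only; floor(train_fraction * n_blocks)
    blocks train, the rest test, chosen by a seeded shuffle.  Blocks at the
    map edge may be ragged; they count as ordinary blocks.
    """
    config.validate()
    blocks = block_index(cells["row"].to_numpy(), cells["col"].to_numpy(),
                         config.block_size_cells)
    uniq = np.unique(blocks)
    if uniq.size < 2:
        raise ValueError(f"need at least 2 non-empty blocks, got {uniq.size}")
    perm = rng.permutation(uniq)
    n_train = int(np.floor(config.train_fraction * uniq.size))
    n_train = min(max(n_train, 1), uniq.size - 1)  # both sides non-empty
    train_blocks = set(perm[:n_train].tolist())
    return np.isin(blocks, list(train_blocks))


def train_bin_model(table: pd.DataFrame, config: ModelConfig,
                    seed: int) -> RandomForestRegressor:
    """Fit the bin's random forest on a training feature table."""
    config.validate()
    if len(table) < config.min_leaf_size:
        raise ValueError(f"too few training rows ({len(table)})")
    model = RandomForestRegressor(
        n_estimators=config.n_trees,
        min_samples_leaf=config.min_leaf_size,
        max_features=config.n_split_vars,
        bootstrap=True,
        random_state=int(seed) % (2 ** 31),
        n_jobs=1,
    )
    model.fit(table[list(MODEL_COVARIATES)].to_numpy(),
              table["yield_t_ha"].to_numpy())
    return model


def _test_metrics(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    denom = float(np.sum((obs - obs.mean()) ** 2))
    nse = 1.0 - float(np.sum((obs - pred) ** 2)) / denom if denom > 0 else np.nan
    return nse, rmse


def run_iterations(features: pd.DataFrame, config: ModelConfig,
                   n_iterations: int | None = None) -> list[IterationResult]:
    """Repeat split -> per-bin fit -> baseline prediction over iterations.

    Iteration seeds are spawned deterministically from ``config.seed``; a
    bin failing its occupancy threshold in one iteration is skipped there
    (its rows predict NaN) without aborting other bins.
    """
    config.validate()
    n_iter = config.n_iterations if n_iterations is None else n_iterations
    X = features[list(MODEL_COVARIATES)].to_numpy()
    results: list[IterationResult] = []
    for it, seq in enumerate(np.random.SeedSequence(config.seed).spawn(n_iter)):
        child_seqs = seq.spawn(2)
        rng = np.random.default_rng(child_seqs[0])
        train_mask = spatial_block_split(features, config, rng)
        fit_seeds = child_seqs[1].generate_state(features["bin_id"].max() + 1)
        models: dict[int, RandomForestRegressor] = {}
        skipped: list[int] = []
        pred = np.full(len(features), np.nan)
        rows = []
        for b, idx in features.groupby("bin_id").indices.items():
            tr = idx[train_mask[idx]]
            te = idx[~train_mask[idx]]
            if tr.size < config.min_bin_rows:
                logger.warning("bin %d skipped: %d training rows < %d",
                               b, tr.size, config.min_bin_rows)
                skipped.append(int(b))
                continue
            model = train_bin_model(features.iloc[tr], config, fit_seeds[int(b)])
            models[int(b)] = model
            pred[idx] = model.predict(X[idx])
            if te.size >= 2:
                nse, rmse = _test_metrics(
                    features["yield_t_ha"].to_numpy()[te], pred[te])
            else:
                nse, rmse = np.nan, np.nan
            rows.append({"bin_id": int(b), "nse": nse, "rmse": rmse,
                         "n_train": int(tr.size), "n_test": int(te.size)})
        results.append(IterationResult(
            iteration=it, models=models, train_mask=train_mask,
            baseline_pred=pred,
            metrics=pd.DataFrame(rows,
                                 columns=["bin_id", "nse", "rmse",
                                          "n_train", "n_test"]),
            skipped_bins=skipped))
    return results
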