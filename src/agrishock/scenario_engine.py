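"""Input-shock scenarios: catalogue, covariate shocking, and scenario prediction.

A scenario multiplies a subset of the shockable covariates (mineral N/P/K,
machinery, the four pesticide groups) by (1 - severity); all other
covariates are untouched in every scenario.  Predictions reuse the fitted
per-bin models of each iteration — the forests are never refitted under a
shock, so a scenario yield is the model's reading of baseline cells whose
input use resembles the shocked cell's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_world import SHOCKABLE_COVARIATES, FROZEN_COVARIATES, MODEL_COVARIATES
from .yield_models import IterationResult

__all__ = ["ShockScenario", "SEVERITIES", "SCENARIO_FAMILIES",
           "scenario_catalogue", "apply_shock", "predict_scenario",
           "yield_change"]

SEVERITIES = (0.25, 0.50, 0.75)

PESTICIDE_COVARIATES = ("pest_herbicide", "pest_insecticide",
                        "pest_fungicide", "pest_other")

#: Scenario family -> covariates shocked together.
SCENARIO_FAMILIES: dict[str, tuple[str, ...]] = {
    "n_shock": ("n_rate",),
    "p_shock": ("p_rate",),
    "k_shock": ("k_rate",),
    "machinery_shock": ("machinery_hp_per_1000ha",),
    "pesticide_shock": PESTICIDE_COVARIATES,
    "fertilizer_shock": ("n_rate", "p_rate", "k_rate"),
    "all_inputs_shock": SHOCKABLE_COVARIATES,
}


@dataclass(frozen=True)
class ShockScenario:
    name: str
    shocked_covariates: tuple[str, ...]
    severity: float
    is_control: bool = field(default=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must be in [0, 1]")
        frozen = set(self.shocked_covariates) & set(FROZEN_COVARIATES)
        if frozen:
            raise ValueError(f"frozen covariates cannot be shocked: {sorted(frozen)}")
        unknown = set(self.shocked_covariates) - set(SHOCKABLE_COVARIATES)
        if unknown:
            raise ValueError(f"unknown shockable covariates: {sorted(unknown)}")


def scenario_catalogue() -> list[ShockScenario]:
    """The 21 shock scenarios (7 families x 3 severities) plus the control.

    The control sets every shockable covariate to zero; it is a robustness
    probe, not part of the severity grid.
    """
    out = [ShockScenario(f"{fam}_{int(sev * 100)}", covs, sev)
           for fam, covs in SCENARIO_FAMILIES.items()
           for sev in SEVERITIES]
    out.append(ShockScenario("control_zero_inputs", SHOCKABLE_COVARIATES,
                             1.0, is_control=True))
    return out


def apply_shock(features: pd.DataFrame, scenario: ShockScenario) -> pd.DataFrame:
    """Feature table with shocked columns scaled by (1 - severity).

    Unshocked columns are carried over without modification (same arrays),
    so frozen covariates are bit-identical across all scenario tables.
    """
    unknown = set(scenario.shocked_covariates) - set(features.columns)
    if unknown:
        raise KeyError(f"covariates not in feature table: {sorted(unknown)}")
    out = features.copy(deep=False)
    for name in scenario.shocked_covariates:
        out[name] = features[name].to_numpy() * (1.0 - scenario.severity)
    return out


def predict_scenario(result: IterationResult, shocked: pd.DataFrame) -> np.ndarray:
    """Per-row scenario yield from one iteration's fitted bin models.

    Rows in bins the iteration skipped come back NaN.  Uses exactly the
    same models as the iteration's baseline predictions.
    """
    pred = np.full(len(shocked), np.nan)
    X = shocked[list(MODEL_COVARIATES)].to_numpy()
    for b, idx in shocked.groupby("bin_id").indices.items():
        model = result.models.get(int(b))
        if model is None:
            continue
        pred[idx] = model.predict(X[idx])
    return pred


def yield_change(baseline: np.ndarray, scenario: np.ndarray,
                 decreases_only: bool = False) -> np.ndarray:
    """Relative change (scenario - baseline)/baseline; NaN where baseline is 0.

    With ``decreases_only`` positive changes are masked to NaN, matching
    map products that display yield losses only.
    """
    baseline = np.asarray(baseline, dtype=float)
    scenario = np.asarray(scenario, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        change = np.where(baseline != 0,
                          (scenario - baseline) / np.where(baseline != 0, baseline, 1),
                          np.nan)
    if decreases_only:
        change = np.where(change > 0, np.nan, change)
    return change
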