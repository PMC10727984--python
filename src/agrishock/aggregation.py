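"""Production accounting: cell, climate-bin, country and global summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import GridField

__all__ = ["production", "country_change", "global_change", "bin_impact_extent"]


def production(yield_t_ha: GridField, harvested_area_ha: GridField) -> GridField:
    """Cellwise production (t) = yield (t/ha) x harvested area (ha)."""
    yield_t_ha.require_aligned(harvested_area_ha)
    y, a = yield_t_ha.values, harvested_area_ha.values
    valid = yield_t_ha.mask & harvested_area_ha.mask
    if (a[valid] < 0).any() or (y[valid] < 0).any():
        raise ValueError("negative yield or area")
    out = GridField(y * a, yield_t_ha.transform,
                    valid & np.isfinite(y * a), "production_t")
    return out


def country_change(baseline_prod: GridField, scenario_prod: GridField,
                   country_id: GridField) -> pd.DataFrame:
    """Per-country production totals and % change (increases included).

    Countries whose baseline production is zero get NaN change and are
    flagged in the ``zero_baseline`` column.
    """
    baseline_prod.require_aligned(scenario_prod)
    baseline_prod.require_aligned(country_id)
    valid = baseline_prod.mask & scenario_prod.mask
    df = pd.DataFrame({
        "country_id": country_id.values[valid].astype(int),
        "baseline_t": baseline_prod.values[valid],
        "scenario_t": scenario_prod.values[valid],
    })
    g = df.groupby("country_id", as_index=False).sum()
    g["zero_baseline"] = g["baseline_t"] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        g["change_pct"] = np.where(
            g["baseline_t"] > 0,
            100.0 * (g["scenario_t"] - g["baseline_t"]) / g["baseline_t"],
            np.nan)
    return g


def global_change(baseline_prod: GridField, scenario_prod: GridField) -> float:
    """Global production change (%) of a scenario relative to baseline."""
    baseline_prod.require_aligned(scenario_prod)
    valid = baseline_prod.mask & scenario_prod.mask
    base = float(baseline_prod.values[valid].sum())
    if base == 0:
        raise ValueError("zero global baseline production")
    scen = float(scenario_prod.values[valid].sum())
    return 100.0 * (scen - base) / base


def bin_impact_extent(baseline_yield: GridField, scenario_yield: GridField,
                      bins, harvested_area: GridField | None = None,
                      threshold: float = 0.10) -> pd.DataFrame:
    """Share (%) of each climate bin where yield drops at least ``threshold``.

    A cell counts as impacted when scenario <= (1 - threshold) * baseline.
    By default the share is weighted by harvested area ("bin area" in the
    crop's sense); pass ``harvested_area=None`` for plain cell counting.
    Bins with no valid cells report NaN.
    """
    baseline_yield.require_aligned(scenario_yield)
    rows = []
    for b in bins.bins():
        sel = bins.cells_in_bin(b)
        base = baseline_yield.values[sel]
        scen = scenario_yield.values[sel]
        ok = np.isfinite(base) & np.isfinite(scen) & (base > 0)
        if harvested_area is not None:
            w = harvested_area.values[sel].astype(float)
        else:
            w = np.ones(sel.sum())
        w = np.where(ok, w, 0.0)
        if w.sum() == 0:
            rows.append({"bin_id": b, "impacted_pct": np.nan, "n_cells": 0})
            continue
        impacted = scen <= (1.0 - threshold) * base
        rows.append({
            "bin_id": b,
            "impacted_pct": 100.0 * float(w[ok & impacted].sum()) / float(w.sum()),
            "n_cells": int(ok.sum()),
        })
    return pd.DataFrame(rows)
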