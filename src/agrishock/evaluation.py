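"""Model-performance metrics and uncertainty quantification.

Nash-Sutcliffe efficiency (NSE) scores held-out predictions per climate
bin, a production-weighted R-squared validates country-mean baseline
yields against a reference, and the coefficient of variation of per-cell
predictions across repeated train/test iterations measures prediction
uncertainty.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["nse", "classify_performance", "weighted_country_r2",
           "prediction_cv", "evaluation_report"]

NSE_VERY_GOOD = 0.75
NSE_GOOD = 0.65


def nse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Nash-Sutcliffe efficiency: 1 - SS_err / SS_obs.

    1 is a perfect fit, 0 matches the mean predictor, negative is worse
    than the mean.  Undefined (raises) when observations are constant.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must be paired")
    if obs.size < 2:
        raise ValueError("need at least 2 pairs")
    denom = float(np.sum((obs - obs.mean()) ** 2))
    if denom == 0:
        raise ValueError("constant observations: NSE undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / denom


def classify_performance(nse_value: float) -> str:
    """'very good' (NSE > 0.75), 'good' (0.65 < NSE <= 0.75), else 'below'."""
    if not np.isfinite(nse_value):
        raise ValueError("NSE must be finite")
    if nse_value > NSE_VERY_GOOD:
        return "very good"
    if nse_value > NSE_GOOD:
        return "good"
    return "below"


def weighted_country_r2(modelled: np.ndarray, reference: np.ndarray,
                        weights: np.ndarray) -> float:
    """Production-weighted R-squared of modelled vs reference country yields.

    The coefficient of determination of the weighted least-squares fit of
    modelled on reference with intercept — equivalently the squared
    weighted Pearson correlation.  Requires >= 3 countries with positive
    weight and non-degenerate weight spread.
    """
    m = np.asarray(modelled, dtype=float)
    r = np.asarray(reference, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (m.shape == r.shape == w.shape):
        raise ValueError("inputs must be aligned")
    if (w < 0).any():
        raise ValueError("negative weights")
    pos = w > 0
    if pos.sum() < 3:
        raise ValueError("need >= 3 countries with positive weight")
    m, r, w = m[pos], r[pos], w[pos]
    wn = w / w.sum()
    if wn.max() > 1 - 1e-12:
        raise ValueError("weights concentrated on a single country")
    mm = m - np.sum(wn * m)
    rr = r - np.sum(wn * r)
    var_m = np.sum(wn * mm ** 2)
    var_r = np.sum(wn * rr ** 2)
    if var_m == 0 or var_r == 0:
        raise ValueError("degenerate (constant) yields under these weights")
    cov = np.sum(wn * mm * rr)
    return float(cov ** 2 / (var_m * var_r))


def prediction_cv(iteration_preds: np.ndarray) -> np.ndarray:
    """Per-cell coefficient of variation across iterations (sd/mean).

    ``iteration_preds`` has iterations on axis 0.  Uses the sample (n-1)
    standard deviation; cells with zero mean come back NaN.
    """
    preds = np.asarray(iteration_preds, dtype=float)
    if preds.shape[0] < 2:
        raise ValueError("need >= 2 iterations")
    flat = preds.reshape(preds.shape[0], -1)
    out = np.full(flat.shape[1], np.nan)
    ok = np.isfinite(flat).sum(axis=0) >= 2
    if ok.any():
        mean = np.nanmean(flat[:, ok], axis=0)
        sd = np.nanstd(flat[:, ok], axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[ok] = np.where(mean != 0, sd / np.where(mean != 0, mean, 1),
                               np.nan)
    return out.reshape(preds.shape[1:])


def pooled_bin_nse(features: pd.DataFrame, iterations) -> pd.Series:
    """Per-bin NSE over all held-out predictions pooled across iterations.

    Each iteration holds out a different 25% of spatial blocks, so pooling
    covers (nearly) the whole bin and gives a far more stable per-bin skill
    estimate than any single iteration's small clustered test set.
    """
    y = features["yield_t_ha"].to_numpy()
    obs: dict[int, list] = {}
    pred: dict[int, list] = {}
    for it in iterations:
        test = ~it.train_mask
        for b, idx in features.groupby("bin_id").indices.items():
            if int(b) not in it.models:
                continue
            sel = idx[test[idx]]
            obs.setdefault(int(b), []).append(y[sel])
            pred.setdefault(int(b), []).append(it.baseline_pred[sel])
    out = {}
    for b in sorted(obs):
        o = np.concatenate(obs[b])
        p = np.concatenate(pred[b])
        out[b] = nse(o, p) if o.size >= 2 and o.std() > 0 else np.nan
    return pd.Series(out, name="nse_pooled")


def evaluation_report(features: pd.DataFrame, iterations) -> pd.DataFrame:
    """Per-bin held-out skill: pooled NSE (headline), iteration-mean NSE and
    RMSE, and the performance class of the pooled value.

    The pooled estimator is the headline because per-iteration test sets at
    modest grid sizes are small and spatially clustered, which makes the
    single-iteration NSE denominator unstable; the iteration-mean column is
    retained for comparability.
    """
    allm = pd.concat([r.metrics for r in iterations], ignore_index=True)
    rep = (allm.groupby("bin_id", as_index=False)
               .agg(nse_iter_mean=("nse", "mean"), rmse=("rmse", "mean"),
                    n_iterations=("nse", "size")))
    pooled = pooled_bin_nse(features, iterations)
    rep.insert(1, "nse", rep["bin_id"].map(pooled))
    rep["class"] = [classify_performance(v) if np.isfinite(v) else "below"
                    for v in rep["nse"]]
    return rep
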