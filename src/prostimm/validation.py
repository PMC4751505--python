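"""Cross-validation of the calibrated model's predictive power.

Two holdout schemes mirror how the model's predictions were originally
stress-tested:

* *leave one condition out* — all data from one treatment arm are held out,
  the model is refit on the remaining arms, and the held-out arm's dynamics
  are predicted;
* *leave one data box out* — only one (condition, observable, time) box is
  held out, so the rest of that arm still informs the fit.

In both schemes the training is repeated with independent GA seeds and the
spread of the replicate predictions yields a 95% normal-theory confidence
band (mean +/- 1.96 sample sd) around the mean prediction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import (
    DEFAULT_BOUNDS,
    GAConfig,
    dataset_objective,
    ga_minimize,
    spawn_seeds,
)
from .model_core import PARAM_NAMES, Regimen, simulate_batch
from .synthetic_data import Dataset, MEASUREMENT_TIMES, OBSERVABLES

__all__ = ["confidence_band", "leave_one_condition_out", "leave_one_box_out",
           "band_coverage"]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile

_OBS_STATE_IDX = {"CTL-P": 12, "Treg-P": 13, "CTL-L": 9, "Treg-L": 10}


def confidence_band(replicate_values) -> tuple[float, float, float]:
    """Normal-theory 95% band over replicate predictions:
    (mean, mean - 1.96 sd, mean + 1.96 sd), with the sample (n-1) sd."""
    v = np.asarray(replicate_values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two replicate values for a band")
    m = float(v.mean())
    half = _Z95 * float(v.std(ddof=1))
    return m, m - half, m + half


def _replicate_predictions(train: Dataset, regimen: Regimen, fit_cfg: GAConfig,
                           replicates: int, seeds, bounds, n_steps: int):
    """Fit ``train`` ``replicates`` times and simulate ``regimen`` with each
    fitted parameter set; returns (replicates, n_times, 5) observables at the
    measurement times."""
    objective = dataset_objective(train, n_steps=n_steps)
    from dataclasses import replace
    fitted = np.empty((replicates, len(PARAM_NAMES)))
    for i, s in enumerate(seeds):
        fit = ga_minimize(objective, bounds, replace(fit_cfg, seed=int(s)),
                          init="loguniform", vectorized=True)
        fitted[i] = fit.x
    states, ok = simulate_batch(fitted, regimen, MEASUREMENT_TIMES,
                                n_steps=n_steps)
    preds = np.empty((replicates, len(MEASUREMENT_TIMES), len(OBSERVABLES)))
    for j, obs in enumerate(OBSERVABLES):
        if obs == "Tumor":
            preds[:, :, j] = (states[:, :, 4] + states[:, :, 5]) / 2.0
        else:
            preds[:, :, j] = states[:, :, _OBS_STATE_IDX[obs]]
    preds[~ok] = np.nan
    return preds


def _band_rows(preds, fold, condition, observed_lookup):
    rows = []
    for ti, t in enumerate(MEASUREMENT_TIMES):
        for oi, obs in enumerate(OBSERVABLES):
            vals = preds[:, ti, oi]
            vals = vals[np.isfinite(vals)]
            if vals.size < 2:
                continue
            m, lo, hi = confidence_band(vals)
            rows.append({"fold": fold, "condition": condition,
                         "observable": obs, "time_weeks": t,
                         "mean": m, "lo95": lo, "hi95": hi,
                         "observed": observed_lookup(condition, obs, t)})
    return rows


def leave_one_condition_out(ds: Dataset, fit_cfg: GAConfig,
                            replicates: int = 20, seed: int = 0,
                            bounds=None, n_steps: int = 250) -> pd.DataFrame:
    """One fold per condition: fit on the other arms, predict the held-out
    arm.  Returns a tidy table (fold, condition, observable, time, mean,
    lo95, hi95, observed) where ``observed`` is the held-out replicate mean
    (NaN for unmeasured boxes)."""
    conditions = ds.conditions
    if len(conditions) < 2:
        raise ValueError("need at least two conditions for condition-wise CV")
    if bounds is None:
        bounds = (np.full(len(PARAM_NAMES), DEFAULT_BOUNDS[0]),
                  np.full(len(PARAM_NAMES), DEFAULT_BOUNDS[1]))
    box_means = {b.key: float(b.values.mean()) for b in ds.boxes}

    def observed(cond, obs, t):
        return box_means.get((cond, obs, t), np.nan)

    rows = []
    for k, cond in enumerate(conditions):
        train = ds.without_condition(cond)
        if len(train) == 0:
            raise ValueError(f"training set empty when holding out {cond}")
        seeds = spawn_seeds(seed, replicates, f"loco-{cond}")
        preds = _replicate_predictions(train, Regimen.from_label(cond),
                                       fit_cfg, replicates, seeds, bounds,
                                       n_steps)
        rows.extend(_band_rows(preds, k, cond, observed))
    return pd.DataFrame(rows)


def leave_one_box_out(ds: Dataset, fit_cfg: GAConfig, replicates: int = 20,
                      seed: int = 0, bounds=None,
                      n_steps: int = 250) -> pd.DataFrame:
    """One fold per data box: fit on everything else, predict that box's
    observable at that time.  The rest of the box's condition stays in
    training."""
    if len(ds) < 2:
        raise ValueError("need at least two boxes for box-wise CV")
    if bounds is None:
        bounds = (np.full(len(PARAM_NAMES), DEFAULT_BOUNDS[0]),
                  np.full(len(PARAM_NAMES), DEFAULT_BOUNDS[1]))
    rows = []
    for k, box in enumerate(ds.boxes):
        train = ds.without_box(box.key)
        seeds = spawn_seeds(seed, replicates, f"lobo-{k}")
        preds = _replicate_predictions(train, Regimen.from_label(box.condition),
                                       fit_cfg, replicates, seeds, bounds,
                                       n_steps)
        ti = MEASUREMENT_TIMES.index(box.time_weeks)
        oi = OBSERVABLES.index(box.observable)
        vals = preds[:, ti, oi]
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            continue
        m, lo, hi = confidence_band(vals)
        rows.append({"fold": k, "condition": box.condition,
                     "observable": box.observable,
                     "time_weeks": box.time_weeks,
                     "mean": m, "lo95": lo, "hi95": hi,
                     "observed": float(box.values.mean())})
    return pd.DataFrame(rows)


def band_coverage(report: pd.DataFrame, reference) -> float:
    """Fraction of report rows whose 95% band covers a reference value.

    ``reference`` maps (condition, observable, time) to the value the band
    should cover — typically the noise-free truth for synthetic data.  Rows
    without a reference entry are skipped.
    """
    hits, total = 0, 0
    for _, row in report.iterrows():
        key = (row["condition"], row["observable"], row["time_weeks"])
        if key not in reference:
            continue
        total += 1
        if row["lo95"] <= reference[key] <= row["hi95"]:
            hits += 1
    if total == 0:
        raise ValueError("no report rows matched the reference table")
    return hits / total
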