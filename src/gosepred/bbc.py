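"""Bootstrap bias-corrected cross-validation inference (BBC-CV / BBCD-CV).

All metrics are computed from *pooled* out-of-fold test-set predictions:
one row per (patient, partition, configuration) across the 100 repeated
cross-validation partitions, so the bootstrap distribution reflects both
resampling and (for imputed predictor sets) imputation variability.

* :func:`bbc_ci` resamples unique patients with replacement (1,000
  resamples by default); each resample carries *all* of a sampled
  patient's pooled rows, the metric is recomputed per resample, and the
  mean with a percentile 95% CI is reported.
* :func:`bbcd_drop` eliminates consistently underperforming parametric
  configurations early: bootstrap the partitions, record which
  configuration wins each resample, and drop configurations whose
  probability of being best falls below ``alpha`` (at least one survivor
  is always kept).
* :func:`select_best` picks the best model per metric; threshold-level
  metrics are judged by their unweighted average across the six thresholds
  (for calibration slope, closest to one; for ICI, smallest).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .metrics import MetricResult

CLASS_PROB_COLUMNS = [f"p{k}" for k in range(1, 8)]
THRESHOLD_PROB_COLUMNS = [f"t{k}" for k in range(1, 7)]


def validate_pooled(pooled: pd.DataFrame, require_config: bool = False) -> None:
    """Check the pooled-prediction invariant: one row per
    (patient, partition[, configuration])."""
    keys = ["patient_id", "partition_id"]
    if require_config or "config_id" in pooled.columns:
        keys.append("config_id")
    if pooled.duplicated(subset=[k for k in keys if k in pooled.columns]).any():
        raise ValueError("duplicate (patient, partition, configuration) rows "
                         "in pooled predictions")


def bbc_ci(pooled: pd.DataFrame, metric: Callable[[pd.DataFrame], float],
           B: int = 1000, seed: int = 0, name: str = "metric",
           threshold: str | None = None) -> MetricResult:
    """Patient-level bootstrap CI for a metric of pooled predictions.

    The resampling unit is the unique patient: a patient's rows across all
    partitions move in and out of a resample together.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    rng = np.random.default_rng([23, seed])
    groups = pooled.groupby("patient_id", sort=True).indices
    ids = np.array(sorted(groups.keys()), dtype=object)
    row_lists = [np.asarray(groups[i]) for i in ids]
    values = np.empty(B)
    for b in range(B):
        take = rng.integers(0, len(ids), size=len(ids))
        rows = np.concatenate([row_lists[j] for j in take])
        values[b] = metric(pooled.iloc[rows])
    lo, hi = np.percentile(values, [2.5, 97.5])
    return MetricResult(name=name, estimate=float(values.mean()),
                        ci_low=float(lo), ci_high=float(hi),
                        distribution=values, threshold=threshold,
                        plugin=float(metric(pooled)))


def bbcd_drop(validation_metrics: np.ndarray, B: int = 1000, alpha: float = 0.01,
              seed: int = 0, higher_is_better: bool = True) -> np.ndarray:
    """Drop configurations that are almost never best on the validation sets.

    ``validation_metrics`` is a (configurations x partitions) matrix. The
    partitions are bootstrapped B times; each resample's winner is the
    configuration with the best mean metric; configurations whose winning
    probability is below ``alpha`` are dropped. Returns the surviving
    configuration indices (never empty).
    """
    M = np.asarray(validation_metrics, dtype=float)
    if M.ndim != 2 or M.size == 0:
        raise ValueError("validation metric matrix must be 2-D and non-empty")
    if M.shape[0] < 2:
        raise ValueError("need at least two configurations to drop from")
    if not higher_is_better:
        M = -M
    rng = np.random.default_rng([29, seed])
    n_cfg, n_part = M.shape
    wins = np.zeros(n_cfg)
    for _ in range(B):
        cols = rng.integers(0, n_part, size=n_part)
        means = M[:, cols].mean(axis=1)
        best = np.flatnonzero(means == means.max())
        wins[best] += 1.0 / len(best)       # split ties evenly
    prob_best = wins / B
    survivors = np.flatnonzero(prob_best >= alpha)
    if survivors.size == 0:
        survivors = np.array([int(np.argmax(prob_best))])
    return survivors


_HIGHER_BETTER = {"orc", "somers_dxy", "c_index"}


def select_best(results: pd.DataFrame) -> dict[str, str]:
    """Best model id per metric from a tidy results table.

    ``results`` columns: model, metric, threshold (empty/NaN for scalar
    metrics), estimate. Scalar metrics use the point estimate directly;
    threshold-level metrics use the unweighted mean across thresholds
    (calibration_slope: minimise |mean - 1|; ici: minimise the mean;
    c_index: maximise the mean). Ties break lexicographically on model id.
    """
    out: dict[str, str] = {}
    for metric, grp in results.groupby("metric"):
        scores = {}
        for model, sub in grp.groupby("model"):
            if sub["threshold"].notna().any() and (sub["threshold"] != "").any():
                value = float(sub["estimate"].mean())
            else:
                value = float(sub["estimate"].iloc[0])
            if metric == "calibration_slope":
                key = -abs(value - 1.0)
            elif metric in _HIGHER_BETTER:
                key = value
            else:                            # ici and other error-like metrics
                key = -value
            scores[str(model)] = key
        # deterministic: among max-score models pick lexicographically first
        top = max(scores.values())
        out[str(metric)] = sorted(m for m, v in scores.items() if v == top)[0]
    return out
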