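"""Ordinal discrimination and calibration metrics.

Discrimination asks how well a model separates patients with different
GOSE categories:

* **ORC** (ordinal c-index): the unweighted mean, over the 21 unordered
  category pairs, of the pairwise Mann-Whitney AUC (ties count 1/2). It is
  the probability of correctly separating two patients drawn from two
  randomly chosen categories, equivalently the average proportional
  correctness of ranking one random patient per category; it is independent
  of category prevalence. No-information value 0.5, perfect 1.
* **Somers' Dxy**: over all patient pairs with different outcomes,
  (concordant - discordant) / (concordant + discordant + score-tied); the
  proportion of ordinal outcome variation explained by the model ranking.
  No-information 0, perfect 1; with two categories Dxy = 2*AUC - 1.
* **Dichotomous c-index**: ordinary AUC at each of the six thresholds.

Calibration asks whether predicted threshold probabilities are reliable:

* **Calibration slope**: slope of the logistic recalibration of observed
  binary outcome on logit(predicted probability); 1 is ideal, < 1 flags
  overfitting (extreme predictions too extreme), > 1 underfitting.
* **Smoothed calibration curve / ICI**: a locally weighted smoother of
  outcome against predicted probability; the integrated calibration index
  is the mean absolute gap between the smoothed curve and the identity over
  the observed predictions (0 is ideal).

Patients are ranked by the expected number of thresholds exceeded
(the sum of the six exceedance probabilities); ORC is invariant to any
strictly increasing transform of the ranking score, so this choice is
innocuous for discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import rankdata

from .probability import N_CATEGORIES, N_THRESHOLDS


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value on the given data."""


@dataclass
class MetricResult:
    """A named metric with its bootstrap distribution and 95% CI."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    distribution: np.ndarray = field(default_factory=lambda: np.array([]))
    threshold: str | None = None
    plugin: float | None = None


def risk_score(probabilities) -> np.ndarray:
    """Expected number of thresholds exceeded, a scalar ranking per patient.

    Accepts (n, 7) category probabilities (accumulated internally) or
    (n, 6) threshold exceedance probabilities.
    """
    p = np.asarray(probabilities, dtype=float)
    single = p.ndim == 1
    if single:
        p = p[None, :]
    if p.shape[1] == N_CATEGORIES:
        if np.any(np.abs(p.sum(axis=1) - 1) > 1e-6) or np.any(p < -1e-9):
            raise ValueError("invalid category probabilities")
        t = 1.0 - np.cumsum(p, axis=1)[:, :-1]
    elif p.shape[1] == N_THRESHOLDS:
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9) or \
                np.any(np.diff(p, axis=1) > 1e-6):
            raise ValueError("invalid threshold probabilities")
        t = p
    else:
        raise ValueError("expected 7 category or 6 threshold probabilities")
    s = t.sum(axis=1)
    return s[0] if single else s


def mann_whitney_auc(scores_neg, scores_pos) -> float:
    """P(score_pos > score_neg) with ties counting one half."""
    neg = np.asarray(scores_neg, dtype=float)
    pos = np.asarray(scores_pos, dtype=float)
    if len(neg) == 0 or len(pos) == 0:
        raise UndefinedMetricError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([neg, pos]))
    u = ranks[len(neg):].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(neg) * len(pos)))


def orc(scores, outcomes) -> float:
    """Ordinal c-index: unweighted mean pairwise AUC over category pairs.

    Category pairs with an empty side are excluded from the mean; all
    patients in a single category is undefined.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes)
    cats = np.unique(outcomes)
    if len(cats) < 2:
        raise UndefinedMetricError("ORC undefined with a single outcome category")
    aucs = [mann_whitney_auc(scores[outcomes == lo], scores[outcomes == hi])
            for lo, hi in combinations(cats, 2)]
    return float(np.mean(aucs))


def somers_dxy(scores, outcomes, chunk: int = 512) -> float:
    """Somers' Dxy = (C - D) / (C + D + T) over cross-outcome patient pairs."""
    s = np.asarray(scores, dtype=float)
    o = np.asarray(outcomes, dtype=float)
    n = len(s)
    C = D = T = 0
    cols = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        rows = np.arange(start, stop)
        pair = (cols[None, :] > rows[:, None]) & (o[start:stop, None] != o[None, :])
        if not pair.any():
            continue
        sgn = (np.sign(s[start:stop, None] - s[None, :])
               * np.sign(o[start:stop, None] - o[None, :]))
        C += int(((sgn > 0) & pair).sum())
        D += int(((sgn < 0) & pair).sum())
        T += int(((sgn == 0) & pair).sum())
    if C + D + T == 0:
        raise UndefinedMetricError("no patient pairs with different outcomes")
    return (C - D) / (C + D + T)


def dichotomous_c_index(threshold_probs, binary_outcomes) -> float:
    """AUC at one GOSE threshold (ties one half); undefined if single-class."""
    p = np.asarray(threshold_probs, dtype=float)
    y = np.asarray(binary_outcomes).astype(int)
    if y.min() == y.max():
        raise UndefinedMetricError("both outcome classes required at the threshold")
    return mann_whitney_auc(p[y == 0], p[y == 1])


def calibration_slope(predicted_probs, binary_outcomes) -> float:
    """Logistic-recalibration slope of outcome on logit(predicted probability)."""
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(binary_outcomes).astype(int)
    if np.ptp(p) == 0:
        raise UndefinedMetricError("constant predictions: slope undefined")
    if y.min() == y.max():
        raise UndefinedMetricError("both outcome classes required")
    lp = logit(np.clip(p, 1e-10, 1 - 1e-10))
    res = sm.Logit(y, sm.add_constant(lp)).fit(disp=0, maxiter=200)
    return float(res.params[1])


def smoothed_calibration_curve(predicted_probs, binary_outcomes,
                               frac: float = 0.75) -> tuple[np.ndarray, np.ndarray, float]:
    """Locally weighted calibration curve and integrated calibration index.

    Returns (sorted predicted probabilities, smoothed observed proportions
    clipped to [0, 1], ICI). ICI is the mean absolute difference between
    the smoothed curve and the predictions, over the observed predictions.
    """
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(binary_outcomes).astype(float)
    if len(p) < 10:
        raise UndefinedMetricError("too few observations for smoothing")
    if np.ptp(p) == 0:
        # closed-form limit: flat smoother at the event rate
        smoothed = np.full_like(p, y.mean())
        return np.sort(p), np.clip(smoothed, 0, 1), float(np.abs(smoothed - p).mean())
    # robustness iterations disabled: with a binary response they bias the
    # smoother towards the majority class
    fitted = sm.nonparametric.lowess(y, p, frac=frac, it=0, return_sorted=True)
    order = np.argsort(p)
    smoothed_sorted = np.clip(np.interp(p[order], fitted[:, 0], fitted[:, 1]), 0, 1)
    ici = float(np.abs(smoothed_sorted - p[order]).mean())
    return p[order], smoothed_sorted, ici


def integrated_calibration_index(predicted_probs, binary_outcomes,
                                 frac: float = 0.75) -> float:
    return smoothed_calibration_curve(predicted_probs, binary_outcomes, frac)[2]
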