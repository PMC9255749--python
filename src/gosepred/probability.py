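"""Probability algebra for the seven-category GOSE outcome.

Six-month functional recovery after traumatic brain injury is scored on the
Glasgow Outcome Scale-Extended (GOSE). Because carer questionnaires cannot
separate the vegetative state (2) from lower severe disability (3), those two
scores are merged, leaving seven ordered categories (1, 2/3, 4, 5, 6, 7, 8)
and six thresholds (GOSE > 1, > 3, > 4, > 5, > 6, > 7).

An ordinal prediction model can encode the outcome two ways:

* **multinomial** -- one node per category, constrained to sum to one by a
  softmax; threshold exceedance probabilities are obtained by accumulating
  category probabilities above each threshold; or
* **ordinal** -- one node per threshold, with monotonicity enforced by
  subtracting a negative-ReLU amount from the previous threshold's
  pre-sigmoid value, so exceedance probabilities can never increase with the
  threshold.

This module holds the pure algebra shared by every model family: the two
output transforms, the conversion between category and threshold
probabilities (exact inverses of each other), conditional exceedance
probabilities, and inverse-frequency class weights.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

GOSE_CATEGORIES: tuple[str, ...] = ("1", "2/3", "4", "5", "6", "7", "8")
GOSE_THRESHOLDS: tuple[str, ...] = (">1", ">3", ">4", ">5", ">6", ">7")
N_CATEGORIES = 7
N_THRESHOLDS = 6


def _as_finite(z, width: int, name: str) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != width:
        raise ValueError(f"{name} must have last dimension {width}, got {z.shape}")
    if not np.all(np.isfinite(z)):
        raise ValueError(f"{name} contains non-finite values")
    return z


def softmax_to_class_probs(z) -> np.ndarray:
    """Map 7 real-valued node outputs to category probabilities.

    Numerically stabilised by subtracting the row maximum before
    exponentiation. Accepts a single 7-vector or an (n, 7) batch.
    """
    z = _as_finite(z, N_CATEGORIES, "z")
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def class_to_threshold_probs(p) -> np.ndarray:
    """Accumulate category probabilities into threshold exceedance probabilities.

    ``P(GOSE > t_k)`` is the sum of category probabilities above threshold k;
    the result is non-increasing in k by construction.
    """
    p = _as_finite(p, N_CATEGORIES, "p")
    if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
        raise ValueError("p is not a valid probability vector over 7 categories")
    c = np.cumsum(p, axis=-1)
    return np.clip(1.0 - c[..., :-1], 0.0, 1.0)


def ordinal_output_transform(z) -> np.ndarray:
    """Constrained-sigmoid ordinal output head.

    The first pre-sigmoid value is ``z_1``; each subsequent one subtracts a
    rectified amount, ``h_k = h_{k-1} - max(z_k, 0)``, so the sigmoid-mapped
    exceedance probabilities are guaranteed non-increasing across thresholds.
    """
    z = _as_finite(z, N_THRESHOLDS, "z")
    h = np.empty_like(z)
    h[..., 0] = z[..., 0]
    for k in range(1, N_THRESHOLDS):
        h[..., k] = h[..., k - 1] - np.maximum(z[..., k], 0.0)
    return expit(h)


def threshold_to_class_probs(t) -> np.ndarray:
    """Difference threshold exceedance probabilities into category probabilities.

    Exact algebraic inverse of :func:`class_to_threshold_probs`:
    ``p_1 = 1 - t_1``, ``p_j = t_{j-1} - t_j``, ``p_7 = t_6``.
    Raises if the input increases across thresholds (invalid exceedance
    curve) or leaves the unit interval.
    """
    t = _as_finite(t, N_THRESHOLDS, "t")
    if np.any(t < -1e-9) or np.any(t > 1 + 1e-9):
        raise ValueError("threshold probabilities must lie in [0, 1]")
    if np.any(np.diff(t, axis=-1) > 1e-9):
        raise ValueError("threshold probabilities must be non-increasing")
    p = np.empty(t.shape[:-1] + (N_CATEGORIES,))
    p[..., 0] = 1.0 - t[..., 0]
    p[..., 1:-1] = t[..., :-1] - t[..., 1:]
    p[..., -1] = t[..., -1]
    return np.clip(p, 0.0, 1.0)


def conditional_probability(t, lower, higher) -> np.ndarray:
    """Conditional exceedance probability Pr(GOSE > higher | GOSE > lower).

    Computed by dividing the exceedance probability at the higher threshold
    by that at the lower threshold. Thresholds may be given as 0-based
    indices or as labels from :data:`GOSE_THRESHOLDS`.
    """
    t = _as_finite(t, N_THRESHOLDS, "t")
    lo = GOSE_THRESHOLDS.index(lower) if isinstance(lower, str) else int(lower)
    hi = GOSE_THRESHOLDS.index(higher) if isinstance(higher, str) else int(higher)
    if not (0 <= lo <= hi < N_THRESHOLDS):
        raise ValueError("lower threshold must precede (or equal) higher threshold")
    p_lo, p_hi = t[..., lo], t[..., hi]
    if np.any(p_lo <= 0):
        raise ZeroDivisionError("conditional probability undefined: P(lower) = 0")
    return np.clip(p_hi / p_lo, 0.0, 1.0)


def class_weights(counts) -> np.ndarray:
    """Inverse-frequency class weights over the 7 categories, mean-normalised.

    ``w_i = n_total / (7 * n_i)`` rescaled so the weights average to one;
    balanced counts give all-ones.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (N_CATEGORIES,):
        raise ValueError(f"expected {N_CATEGORIES} category counts")
    if np.any(counts < 1):
        raise ValueError("every category must have at least one patient")
    w = counts.sum() / (N_CATEGORIES * counts)
    return w / w.mean()
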