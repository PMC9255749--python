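"""Shapley-value token attribution and extended-predictor-set selection.

For a token-embedding model, the contribution of each token towards a
chosen model output (a category probability or a threshold exceedance
probability) is measured by its Shapley value: the average marginal change
in the output when the token is added to a random coalition of the
patient's other tokens. Removing a token means dropping it from the set
and decrementing the token count N in the weighted average; the empty set
aggregates to the zero vector, the model's no-information reference.

Shapley values are estimated by Monte-Carlo permutation sampling (default
128 permutations per patient), which is exact when all permutations of a
small token set are enumerated. Importance is then aggregated bottom-up:
absolute values -> mean over partitions per (patient, token) -> mean over
patients per token -> predictor score = maximum over the predictor's
tokens. Tokens a patient never had contribute nothing to that patient's
mean (no zero padding).

Predictor-class filtering removes treatment/intervention and
physician-impression predictors before candidate ranking: impressions
summarise clinician judgement that can feed self-fulfilling prophecies
(e.g. prognosis-driven withdrawal of life-sustaining measures), so they
are excluded from an extended predictor set by design.
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd


def shapley_token_attribution(value_fn: Callable[[frozenset], float],
                              tokens: Iterable, n_permutations: int = 128,
                              seed: int = 0,
                              exhaustive: bool | None = None) -> dict:
    """Per-token Shapley attribution of ``value_fn`` over a token set.

    ``value_fn`` maps a frozenset of tokens (possibly empty) to a scalar
    model output; evaluations are memoised. With ``exhaustive`` (the
    default whenever all permutations fit inside ``n_permutations``) every
    ordering is enumerated and the result is exact; otherwise orderings are
    sampled uniformly. The attributions satisfy the efficiency axiom:
    their sum equals value(full set) - value(empty set) exactly under
    exhaustive enumeration.
    """
    tokens = list(tokens)
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if not tokens:
        return {}
    cache: dict[frozenset, float] = {}

    def value(subset: frozenset) -> float:
        if subset not in cache:
            cache[subset] = float(value_fn(subset))
        return cache[subset]

    n_total = math.factorial(len(tokens))
    if exhaustive is None:
        exhaustive = n_total <= n_permutations
    if exhaustive:
        orderings: Iterable = permutations(tokens)
        n_orders = n_total
    else:
        rng = np.random.default_rng([31, seed])
        orderings = (list(rng.permutation(np.arange(len(tokens))))
                     for _ in range(n_permutations))
        orderings = ([tokens[i] for i in order] for order in orderings)
        n_orders = n_permutations
    totals = {t: 0.0 for t in tokens}
    for order in orderings:
        subset: frozenset = frozenset()
        prev = value(subset)
        for t in order:
            subset = subset | {t}
            cur = value(subset)
            totals[t] += cur - prev
            prev = cur
    return {t: v / n_orders for t, v in totals.items()}


def aggregate_importance(attributions: pd.DataFrame,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-(patient, partition, token) attributions.

    Input columns: patient_id, partition_id, token, value. Returns
    (token table with columns token, predictor, score sorted descending;
    predictor table with columns predictor, score, top_token).
    The predictor name is the token prefix before the final underscore.
    """
    if attributions.empty:
        raise ValueError("no attributions to aggregate")
    df = attributions.copy()
    df["abs_value"] = df["value"].abs()
    per_patient = (df.groupby(["patient_id", "token"], sort=False)["abs_value"]
                   .mean().reset_index())
    token_scores = (per_patient.groupby("token")["abs_value"].mean()
                    .rename("score").reset_index())
    token_scores["predictor"] = token_scores["token"].str.rsplit("_", n=1).str[0]
    token_scores = token_scores.sort_values("score", ascending=False,
                                            ignore_index=True)
    idx = token_scores.groupby("predictor")["score"].idxmax()
    predictor_scores = token_scores.loc[idx, ["predictor", "score", "token"]]
    predictor_scores = predictor_scores.rename(columns={"token": "top_token"})
    predictor_scores = predictor_scores.sort_values("score", ascending=False,
                                                    ignore_index=True)
    return token_scores, predictor_scores


def filter_predictor_classes(predictor_table: pd.DataFrame,
                             class_labels: Mapping[str, Iterable[str]],
                             excluded: Iterable[str],
                             k: int = 8) -> pd.DataFrame:
    """Rank extended-set candidates after removing excluded predictor classes.

    Every predictor must be labelled (e.g. 'treatment', 'physician
    impression', or token-type labels); the top ``k`` remaining predictors
    (default 8, the number of high-impact additions that formed the
    extended concise set) are returned. Excluded predictors are recorded
    in the ``excluded_`` attribute-like audit column of the returned frame
    via ``frame.attrs['excluded']``.
    """
    excluded = set(excluded)
    labels = {p: set(v) for p, v in class_labels.items()}
    missing = [p for p in predictor_table["predictor"] if p not in labels]
    if missing:
        raise KeyError(f"unlabelled predictors: {missing[:5]}")
    drop_mask = predictor_table["predictor"].map(
        lambda p: bool(labels[p] & excluded))
    kept = predictor_table[~drop_mask].head(k).reset_index(drop=True)
    kept.attrs["excluded"] = predictor_table.loc[drop_mask, "predictor"].tolist()
    if kept.empty:
        warnings.warn("all predictors excluded by class filter", UserWarning,
                      stacklevel=2)
    return kept
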