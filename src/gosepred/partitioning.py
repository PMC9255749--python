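"""Repeated stratified k-fold resampling scaffold.

The analysis design is 20 repeats of stratified 5-fold cross-validation
(100 partitions). Within a repeat the five test folds are disjoint and
cover the cohort; stratification is by the seven-category ordinal outcome,
so every fold preserves category proportions to within one patient.
Parametric (gradient-trained) models additionally carve a stratified
validation split out of each training set for early stopping and
hyperparameter selection, drawn before any imputation is fitted so nothing
leaks into the stopping rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedShuffleSplit


class StratificationError(ValueError):
    """Raised when an outcome category is too small to stratify."""


@dataclass
class Partition:
    repeat: int
    fold: int
    train_ids: list[str]
    test_ids: list[str]
    val_ids: list[str] = field(default_factory=list)


@dataclass
class PartitionScheme:
    """All train/test (and optional validation) index sets of one design."""

    repeats: int
    folds: int
    seed: int
    partitions: list[Partition]

    def __len__(self) -> int:
        return len(self.partitions)

    def to_json(self, path) -> None:
        payload = {
            "repeats": self.repeats, "folds": self.folds, "seed": self.seed,
            "partitions": [
                {"repeat": p.repeat, "fold": p.fold, "train": p.train_ids,
                 "test": p.test_ids, "val": p.val_ids}
                for p in self.partitions
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PartitionScheme":
        with open(path) as fh:
            payload = json.load(fh)
        parts = [Partition(p["repeat"], p["fold"], p["train"], p["test"],
                           p.get("val", []))
                 for p in payload["partitions"]]
        return cls(payload["repeats"], payload["folds"], payload["seed"], parts)


def make_repeated_stratified_kfold(outcomes: pd.Series, repeats: int = 20,
                                   folds: int = 5, seed: int = 0) -> PartitionScheme:
    """Create repeats x folds stratified partitions of the cohort.

    ``outcomes`` is a Series of category codes indexed by patient id.
    Every category must have at least ``folds`` members.
    """
    y = outcomes.to_numpy()
    ids = np.asarray(outcomes.index, dtype=object)
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        small = counts[counts < folds].index.tolist()
        raise StratificationError(
            f"outcome categories {small} have fewer members than folds={folds}")
    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                   random_state=seed)
    partitions = []
    for k, (train_idx, test_idx) in enumerate(rskf.split(np.zeros(len(y)), y)):
        partitions.append(Partition(
            repeat=k // folds, fold=k % folds,
            train_ids=list(ids[train_idx]), test_ids=list(ids[test_idx])))
    return PartitionScheme(repeats=repeats, folds=folds, seed=seed,
                           partitions=partitions)


def make_validation_split(train_ids, outcomes: pd.Series, fraction: float = 0.15,
                          seed: int = 0) -> tuple[list[str], list[str]]:
    """Stratified shuffle split of a training set into inner-train/validation.

    The validation set holds round(fraction x |train|) patients (at least
    one); used only by gradient-trained models for early stopping.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("validation fraction must lie strictly in (0, 1)")
    train_ids = list(train_ids)
    y = outcomes.loc[train_ids].to_numpy()
    n_val = max(1, int(round(fraction * len(train_ids))))
    classes, counts = np.unique(y, return_counts=True)
    if n_val < len(classes) or (counts < 2).any():
        raise StratificationError(
            "validation split too small to hold every outcome stratum")
    sss = StratifiedShuffleSplit(n_splits=1, test_size=n_val, random_state=seed)
    inner_idx, val_idx = next(sss.split(np.zeros(len(y)), y))
    return ([train_ids[i] for i in inner_idx], [train_ids[i] for i in val_idx])
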