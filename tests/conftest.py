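"""Shared fixtures: small seeded synthetic cohorts and brute-force oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

import gosepred as g


def brute_orc(scores, outcomes) -> float:
    """Independent oracle: unweighted mean pairwise AUC by full enumeration."""
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes)
    cats = np.unique(outcomes)
    aucs = []
    for lo, hi in combinations(cats, 2):
        a = scores[outcomes == lo]
        b = scores[outcomes == hi]
        total = 0.0
        for x in a:
            for z in b:
                total += 1.0 if z > x else (0.5 if z == x else 0.0)
        aucs.append(total / (len(a) * len(b)))
    return float(np.mean(aucs))


def brute_dxy(scores, outcomes) -> float:
    """Independent oracle: Somers' Dxy by full pair enumeration."""
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes)
    C = D = T = 0
    n = len(scores)
    for i in range(n):
        for j in range(i + 1, n):
            if outcomes[i] == outcomes[j]:
                continue
            prod = np.sign(scores[i] - scores[j]) * np.sign(outcomes[i] - outcomes[j])
            if prod > 0:
                C += 1
            elif prod < 0:
                D += 1
            else:
                T += 1
    return (C - D) / (C + D + T)


@pytest.fixture(scope="session")
def complete_cohort():
    """Mode-B cohort, n=600, no missingness."""
    cfg = g.default_config(n_patients=600, seed=11, with_missingness=False)
    return g.generate_concise_cohort(cfg)


@pytest.fixture(scope="session")
def masked_cohort():
    """Mode-B cohort, n=600, default missingness applied."""
    cfg = g.default_config(n_patients=600, seed=11)
    return g.apply_missingness(g.generate_concise_cohort(cfg))


@pytest.fixture(scope="session")
def fitted_design(complete_cohort):
    """Design matrix + outcomes for the complete cohort (full one-hot)."""
    table = complete_cohort.table.set_index("patient_id")
    builder = g.DesignMatrixBuilder(complete_cohort.config.schema).fit(table)
    return builder.transform(table), table["outcome"].to_numpy(int)


@pytest.fixture(scope="session")
def small_records():
    """Scaled-down heterogeneous records with planted signal, plus kind map."""
    cfg = g.default_config(n_patients=500, seed=23, with_missingness=False)
    cohort = g.generate_concise_cohort(cfg)
    spec = g.HeterogeneousRecordSpec().scaled(0.05)
    records = g.generate_heterogeneous_records(cfg, cohort, spec)
    return cohort, spec, records
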