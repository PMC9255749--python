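"""Descriptive statistics and pooled inference for cohort reporting.

Covers the arithmetic of the study-inclusion flow (exclusion cascade,
observed-outcome fraction, fraction of ICU deaths preceded by withdrawal of
life-sustaining measures) and the pooled proportional-odds p-values that
annotate descriptive tables: one ordinal regression on all predictors
concurrently per imputed dataset, with Wald tests for scalar predictors and
likelihood-ratio tests (k-1 degrees of freedom) for multi-categorical ones,
combined across the multiple imputations by the z-transformation rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .impute import DesignMatrixBuilder
from .models import ProportionalOddsLogit


@dataclass(frozen=True)
class CohortFlow:
    """Study-inclusion cascade and follow-up counts of the reference cohort."""

    screened: int = 2138
    excluded_age: int = 82          # under 16 years at ICU admission
    excluded_no_outcome: int = 283  # no follow-up outcome available
    excluded_short_stay: int = 223  # ICU stay under 24 hours
    died_icu: int = 205
    followed_up: int = 1146         # outcome observed in the 5-8 month window
    wlsm_among_died: int = 144      # withdrawal of life-sustaining measures

    @property
    def n_study(self) -> int:
        return (self.screened - self.excluded_age - self.excluded_no_outcome
                - self.excluded_short_stay)

    @property
    def n_observed(self) -> int:
        """Patients whose outcome needs no statistical imputation."""
        return self.died_icu + self.followed_up

    @property
    def observed_fraction_pct(self) -> float:
        return 100.0 * self.n_observed / self.n_study

    @property
    def wlsm_fraction_pct(self) -> float:
        return 100.0 * self.wlsm_among_died / self.died_icu


def pool_z_transform(pvalues) -> float:
    """Combine one test's p-values across imputations via z-transformation.

    Each p-value is mapped to a standard-normal quantile; the mean z is
    shrunk by the between-imputation variance, ``z_pool = mean(z) /
    sqrt(1 + var(z))``, and mapped back to a p-value. With a single
    imputation the pooled p equals the input p.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to pool")
    z = norm.isf(np.clip(p, 1e-300, 1 - 1e-16))
    between = z.var(ddof=1) if len(z) > 1 else 0.0
    z_pool = z.mean() / np.sqrt(1.0 + between)
    return float(norm.sf(z_pool))


def polr_pvalues(completed_tables, schema, outcome_col: str = "outcome",
                 ) -> pd.DataFrame:
    """Per-predictor pooled p-values from proportional-odds fits.

    One ordinal regression on all predictors concurrently per completed
    (imputed) table; scalar predictors get Wald z tests, multi-categorical
    predictors get likelihood-ratio tests with k-1 degrees of freedom.
    Imputations whose fit fails to converge are excluded with a warning.
    """
    per_imputation: dict[str, list[float]] = {s.name: [] for s in schema}
    n_used = 0
    for table in completed_tables:
        builder = DesignMatrixBuilder(schema, drop_first=True).fit(table)
        X = builder.transform(table)
        y = table[outcome_col].to_numpy(dtype=int)
        full = ProportionalOddsLogit().fit(X, y)
        if not full.converged_:
            warnings.warn("excluding a non-converged imputation from pooling",
                          UserWarning, stacklevel=2)
            continue
        n_used += 1
        for spec in schema:
            if spec.kind == "categorical" and len(spec.levels) > 2:
                cols = [c for c in X.columns if c.startswith(f"{spec.name}=")]
                reduced = ProportionalOddsLogit().fit(X.drop(columns=cols), y)
                lr = 2.0 * (full.llf_ - reduced.llf_)
                p = float(chi2.sf(max(lr, 0.0), df=len(cols)))
            else:
                z = full.coef_[spec.name] / full.bse_[spec.name]
                p = float(2 * norm.sf(abs(z)))
            per_imputation[spec.name].append(p)
    if n_used == 0:
        raise RuntimeError("no imputation produced a converged fit")
    rows = [{"predictor": name, "p_value": pool_z_transform(ps),
             "n_imputations": len(ps)}
            for name, ps in per_imputation.items()]
    return pd.DataFrame(rows)
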