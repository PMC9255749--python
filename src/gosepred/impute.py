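"""Stochastic predictive-mean-matching imputation and design-matrix building.

Each cross-validation partition gets its own imputation model, fitted
exclusively on that partition's training rows, then used to complete both
the training and the test table. Repeating this across 100 partitions
yields a multiply imputed (m = 100) dataset in which resampling variability
and imputation variability are accounted for together.

Predictive mean matching (PMM) runs chained equations: each incomplete
variable is regressed on all the others (plus, by default, the outcome when
fitting on training rows), a stochastic draw of the regression coefficients
produces predicted means for the missing cells, and each missing cell is
filled with the *observed* value of one of the k nearest training donors by
predicted mean. Because donors are observed values, imputed categoricals
are always valid levels and continuous imputations stay in range.

Test tables are completed with outcome-free models refitted on the
completed training data, so no outcome information flows into test-set
predictors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


class ImputationError(ValueError):
    pass


def _ols_fit(X: np.ndarray, y: np.ndarray):
    """Least squares with ridge jitter for numerical safety; returns
    (beta_hat, XtX_inv, sigma2)."""
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    return beta, XtX_inv, sigma2, dof


def _draw_beta(beta, XtX_inv, sigma2, dof, rng):
    """Approximate Bayesian draw of the regression coefficients."""
    s2 = sigma2 * dof / max(rng.chisquare(dof), 1e-12)
    cov = s2 * XtX_inv
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(beta)))
    return beta + L @ rng.standard_normal(len(beta))


class PMMImputer(BaseEstimator, TransformerMixin):
    """Chained-equations predictive mean matching imputer.

    Parameters
    ----------
    donors : int
        Donor pool size per missing cell (k nearest by predicted mean).
    iterations : int
        Chained-equation sweeps; variables are visited in order of
        increasing missingness.
    include_outcome : bool
        Include the outcome column as a covariate when fitting on and
        completing the training table (test completion is always
        outcome-free).
    categorical_cols : sequence of str, optional
        Columns whose imputations must be valid observed levels; unseen
        observed levels at transform time are mapped to the training modal
        level with a warning.
    random_state : int
    """

    def __init__(self, donors: int = 5, iterations: int = 10,
                 include_outcome: bool = True, categorical_cols=None,
                 outcome_col: str = "outcome", random_state: int = 0):
        self.donors = donors
        self.iterations = iterations
        self.include_outcome = include_outcome
        self.categorical_cols = categorical_cols
        self.outcome_col = outcome_col
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        cols = [c for c in X.columns if c != self.outcome_col]
        work = X[cols].astype(float).copy()
        if self.include_outcome and self.outcome_col in X.columns:
            work[self.outcome_col] = X[self.outcome_col].astype(float)
        rng = np.random.default_rng([11, self.random_state])

        obs_mask = X[cols].notna()
        for c in cols:
            n_obs = int(obs_mask[c].sum())
            if n_obs == 0:
                raise ImputationError(f"variable {c!r} is fully missing in training set")
            if n_obs < self.donors:
                raise ImputationError(
                    f"variable {c!r} has fewer observed training values "
                    f"({n_obs}) than donors ({self.donors})")

        self.columns_ = cols
        self.observed_values_ = {c: X.loc[obs_mask[c], c].to_numpy(dtype=float)
                                 for c in cols}
        self.visit_order_ = sorted(
            [c for c in cols if (~obs_mask[c]).any()],
            key=lambda c: (~obs_mask[c]).sum())

        # initialise missing cells with random observed draws
        for c in self.visit_order_:
            miss = ~obs_mask[c].to_numpy()
            work.loc[miss, c] = rng.choice(self.observed_values_[c], size=miss.sum())

        for _ in range(self.iterations):
            for c in self.visit_order_:
                self._pmm_sweep(work, obs_mask, c, rng)

        # outcome-free models on the completed training data, for test-set use
        self.models_ = {}
        for c in cols:
            others = [o for o in cols if o != c]
            Xd = np.column_stack([np.ones(len(work)), work[others].to_numpy()])
            yv = work[c].to_numpy()
            obs = obs_mask[c].to_numpy()
            beta, XtX_inv, sigma2, dof = _ols_fit(Xd[obs], yv[obs])
            donor_yhat = Xd[obs] @ beta
            self.models_[c] = {
                "others": others, "beta": beta, "XtX_inv": XtX_inv,
                "sigma2": sigma2, "dof": dof,
                "donor_yhat": donor_yhat, "donor_values": yv[obs],
            }

        self.training_completed_ = work[cols].copy()
        if self.outcome_col in X.columns:
            self.training_completed_[self.outcome_col] = X[self.outcome_col].values
        cats = list(self.categorical_cols or [])
        self.modal_levels_ = {
            c: float(pd.Series(self.observed_values_[c]).mode().iloc[0])
            for c in cats}
        self.level_sets_ = {c: set(np.unique(self.observed_values_[c]))
                            for c in cats}
        return self

    def _pmm_sweep(self, work, obs_mask, col, rng):
        others = [c for c in work.columns if c != col]
        Xd = np.column_stack([np.ones(len(work)), work[others].to_numpy()])
        yv = work[col].to_numpy()
        obs = obs_mask[col].to_numpy()
        beta, XtX_inv, sigma2, dof = _ols_fit(Xd[obs], yv[obs])
        beta_star = _draw_beta(beta, XtX_inv, sigma2, dof, rng)
        yhat_obs = Xd[obs] @ beta            # donors matched on ML fit
        yhat_mis = Xd[~obs] @ beta_star      # stochastic draw for targets
        work.loc[~obs, col] = _pmm_match(yhat_mis, yhat_obs, yv[obs],
                                         self.donors, rng)

    # -- completion --------------------------------------------------------

    def transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        """Complete a table with the same predictor schema.

        Observed cells are passed through unchanged; missing cells are
        filled with observed training donor values. Stochastic but
        deterministic for a fitted imputer and a fixed input.
        """
        check_is_fitted(self, "models_")
        missing_schema = set(self.columns_) - set(X.columns)
        if missing_schema:
            raise ImputationError(f"table lacks fitted columns {sorted(missing_schema)}")
        out = X.copy()
        work = out[self.columns_].astype(float).copy()
        rng = np.random.default_rng([13, self.random_state])

        # unseen observed categorical levels -> training modal level
        for c, levels in self.level_sets_.items():
            vals = work[c]
            bad = vals.notna() & ~vals.isin(levels)
            if bad.any():
                warnings.warn(
                    f"{int(bad.sum())} unseen level(s) of {c!r} mapped to the "
                    f"training modal level", UserWarning, stacklevel=2)
                work.loc[bad, c] = self.modal_levels_[c]

        obs_mask = work.notna()
        to_visit = [c for c in self.columns_ if (~obs_mask[c]).any()]
        # initialise with random training-observed draws, then sweep
        for c in to_visit:
            miss = ~obs_mask[c].to_numpy()
            work.loc[miss, c] = rng.choice(self.observed_values_[c], size=miss.sum())
        for _ in range(self.iterations):
            for c in to_visit:
                m = self.models_[c]
                Xd = np.column_stack([np.ones(len(work)),
                                      work[m["others"]].to_numpy()])
                beta_star = _draw_beta(m["beta"], m["XtX_inv"], m["sigma2"],
                                       m["dof"], rng)
                miss = ~obs_mask[c].to_numpy()
                yhat_mis = Xd[miss] @ beta_star
                work.loc[miss, c] = _pmm_match(yhat_mis, m["donor_yhat"],
                                               m["donor_values"], self.donors, rng)
        for c in self.columns_:
            out[c] = work[c]
        return out


def _pmm_match(yhat_mis, yhat_obs, values_obs, donors, rng):
    """For each target predicted mean, draw one of the k nearest donors."""
    order = np.argsort(yhat_obs)
    sorted_yhat = yhat_obs[order]
    sorted_vals = values_obs[order]
    k = min(donors, len(sorted_vals))
    pos = np.searchsorted(sorted_yhat, yhat_mis)
    filled = np.empty(len(yhat_mis))
    for i, (p, ym) in enumerate(zip(pos, yhat_mis)):
        lo = max(0, p - k)
        hi = min(len(sorted_yhat), p + k)
        window = np.arange(lo, hi)
        nearest = window[np.argsort(np.abs(sorted_yhat[window] - ym))[:k]]
        filled[i] = sorted_vals[rng.choice(nearest)]
    return filled


def fit_pmm(train_table: pd.DataFrame, categorical_cols=None, iterations: int = 10,
            donors: int = 5, seed: int = 0, include_outcome: bool = True,
            outcome_col: str = "outcome") -> PMMImputer:
    """Fit a PMM imputation model on training rows only."""
    imp = PMMImputer(donors=donors, iterations=iterations,
                     include_outcome=include_outcome,
                     categorical_cols=categorical_cols,
                     outcome_col=outcome_col, random_state=seed)
    return imp.fit(train_table)


def impute(model: PMMImputer, table: pd.DataFrame) -> pd.DataFrame:
    """Complete a table using a fitted imputation model."""
    return model.transform(table)


class DesignMatrixBuilder(BaseEstimator, TransformerMixin):
    """Prepare a completed table for model fitting.

    Multi-categorical predictors (3+ levels) are one-hot encoded; binary
    predictors become single 0/1 columns; continuous predictors are
    standardised with the *training* mean and SD. ``drop_first=True`` drops
    each one-hot group's reference level (required by cumulative-link
    models, whose thresholds absorb the intercept).
    """

    def __init__(self, schema, drop_first: bool = False):
        self.schema = schema
        self.drop_first = drop_first

    def fit(self, X: pd.DataFrame, y=None):
        self.stats_ = {}
        for spec in self.schema:
            if spec.kind == "continuous":
                col = X[spec.name].to_numpy(dtype=float)
                if np.isnan(col).any():
                    raise ValueError(f"column {spec.name!r} incomplete at fit time")
                mu, sd = float(col.mean()), float(col.std(ddof=0))
                if sd == 0:
                    raise ValueError(f"zero training SD for {spec.name!r}")
                self.stats_[spec.name] = (mu, sd)
        self.feature_names_ = []
        for spec in self.schema:
            if spec.kind == "categorical" and len(spec.levels) > 2:
                levels = spec.levels[1:] if self.drop_first else spec.levels
                self.feature_names_ += [f"{spec.name}={lv}" for lv in levels]
            else:
                self.feature_names_.append(spec.name)
        return self

    def transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        check_is_fitted(self, "stats_")
        cols = {}
        for spec in self.schema:
            x = X[spec.name].to_numpy(dtype=float)
            if np.isnan(x).any():
                raise ValueError(f"column {spec.name!r} contains missing values; "
                                 "impute before building the design matrix")
            if spec.kind == "continuous":
                mu, sd = self.stats_[spec.name]
                cols[spec.name] = (x - mu) / sd
            elif spec.kind == "categorical" and len(spec.levels) > 2:
                levels = spec.levels[1:] if self.drop_first else spec.levels
                for lv in levels:
                    cols[f"{spec.name}={lv}"] = (x == float(lv)).astype(float)
            else:
                cols[spec.name] = x
        return pd.DataFrame(cols, index=X.index)[self.feature_names_]


def build_design_matrix(completed: pd.DataFrame, schema,
                        builder: DesignMatrixBuilder | None = None,
                        drop_first: bool = False) -> tuple[pd.DataFrame, DesignMatrixBuilder]:
    """One-hot/standardise a completed table; fits the builder if not given.

    Returns (design matrix, fitted builder); pass the returned builder when
    transforming test rows so they are scaled with training statistics.
    """
    if builder is None:
        builder = DesignMatrixBuilder(schema, drop_first=drop_first).fit(completed)
    return builder.transform(completed), builder
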