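"""PMM imputation and design-matrix preparation."""

import numpy as np
import pandas as pd
import pytest

import gosepred as g
from gosepred.impute import ImputationError


def _mcar_frame(n=300, miss=0.3, seed=0):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0, 1, n)
    x2 = 0.8 * x1 + rng.normal(0, 0.6, n)
    y = (x1 + x2 + rng.normal(0, 1, n) > 0).astype(int) + 1
    df = pd.DataFrame({"x1": x1, "x2": x2, "outcome": y})
    mask = rng.uniform(size=n) < miss
    df.loc[mask, "x2"] = np.nan
    return df, x2, mask


class TestPMMImputer:
    def test_complete_table_is_identity(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6], "b": [2.0, 1, 4, 3, 6, 5]})
        imp = g.PMMImputer(donors=2, iterations=2).fit(df)
        out = imp.transform(df)
        pd.testing.assert_frame_equal(out, df)

    def test_observed_cells_unchanged(self):
        df, truth, mask = _mcar_frame()
        imp = g.PMMImputer(random_state=1).fit(df)
        out = imp.transform(df.drop(columns=["outcome"]))
        np.testing.assert_allclose(out.loc[~mask, "x2"], truth[~mask])
        assert out["x2"].notna().all()

    def test_imputed_values_are_training_donors(self):
        df, _, mask = _mcar_frame()
        imp = g.PMMImputer(random_state=1).fit(df)
        done = imp.training_completed_
        observed = set(df.loc[~mask, "x2"])
        assert set(done.loc[mask, "x2"]).issubset(observed)

    def test_mcar_mean_recovery_within_three_se(self):
        """Imputed-value mean tracks the truth mean across seeds (simulation
        oracle for unbiasedness under MCAR)."""
        means, truths = [], []
        for seed in range(20):
            df, truth, mask = _mcar_frame(seed=seed)
            imp = g.PMMImputer(iterations=5, random_state=seed).fit(df)
            means.append(imp.training_completed_.loc[mask, "x2"].mean())
            truths.append(truth[mask].mean())
        diff = np.array(means) - np.array(truths)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se + 0.05

    def test_two_seeds_differ_on_missing_cells_only(self):
        df, _, mask = _mcar_frame()
        out1 = g.PMMImputer(random_state=1).fit(df).training_completed_
        out2 = g.PMMImputer(random_state=2).fit(df).training_completed_
        np.testing.assert_allclose(out1.loc[~mask, "x2"], out2.loc[~mask, "x2"])
        assert not np.allclose(out1.loc[mask, "x2"], out2.loc[mask, "x2"])

    def test_degenerate_donor_pool(self):
        df = pd.DataFrame({"a": np.arange(10.0),
                           "b": [1.0, 2.0, 3.0, 4.0, 5.0] + [np.nan] * 5})
        imp = g.PMMImputer(donors=5, iterations=2, random_state=0).fit(df)
        filled = imp.training_completed_["b"]
        assert set(filled).issubset({1.0, 2.0, 3.0, 4.0, 5.0})

    def test_fully_missing_variable_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [np.nan] * 3})
        with pytest.raises(ImputationError):
            g.PMMImputer().fit(df)

    def test_categorical_imputations_are_valid_levels(self, masked_cohort):
        table = masked_cohort.table.set_index("patient_id")
        cats = [s.name for s in masked_cohort.config.schema
                if s.kind in ("categorical", "binary")]
        imp = g.PMMImputer(categorical_cols=cats, iterations=3,
                           random_state=0).fit(table)
        done = imp.training_completed_
        for spec in masked_cohort.config.schema:
            if spec.kind in ("categorical", "binary"):
                assert set(done[spec.name]).issubset(set(map(float, spec.levels)))

    def test_no_leakage_from_test_rows(self, masked_cohort):
        """The fitted imputation model depends only on training rows."""
        table = masked_cohort.table.set_index("patient_id")
        train = table.iloc[:400]
        imp_a = g.PMMImputer(iterations=2, random_state=0).fit(train)
        imp_b = g.PMMImputer(iterations=2, random_state=0).fit(train.copy())
        test = table.iloc[400:].drop(columns=["outcome"])
        pd.testing.assert_frame_equal(imp_a.transform(test), imp_b.transform(test))
        pd.testing.assert_frame_equal(imp_a.training_completed_,
                                      imp_b.training_completed_)

    def test_unseen_level_maps_to_modal_with_warning(self):
        df = pd.DataFrame({"a": np.arange(20.0),
                           "c": [1.0] * 12 + [2.0] * 7 + [np.nan]})
        imp = g.PMMImputer(categorical_cols=["c"], iterations=2,
                           random_state=0).fit(df)
        new = pd.DataFrame({"a": [0.0], "c": [9.0]})
        with pytest.warns(UserWarning, match="unseen level"):
            out = imp.transform(new)
        assert out.loc[0, "c"] == 1.0


class TestDesignMatrix:
    def test_multicategorical_one_hot_group(self, complete_cohort,
                                            fitted_design):
        X, _ = fitted_design
        gcs_cols = [c for c in X.columns if c.startswith("GCSm=")]
        assert len(gcs_cols) == 6
        np.testing.assert_allclose(X[gcs_cols].sum(axis=1), 1.0)

    def test_training_columns_standardised(self, fitted_design):
        X, _ = fitted_design
        for col in ("age", "glucose", "hb"):
            assert abs(X[col].mean()) < 1e-8
            assert abs(X[col].std(ddof=0) - 1) < 1e-8

    def test_binary_predictors_single_column(self, fitted_design):
        X, _ = fitted_design
        for col in ("hypoxia", "hypotension", "tsah", "edh"):
            assert col in X.columns
            assert set(np.unique(X[col])) <= {0.0, 1.0}

    def test_test_rows_scaled_with_training_statistics(self, complete_cohort):
        table = complete_cohort.table.set_index("patient_id")
        schema = complete_cohort.config.schema
        builder = g.DesignMatrixBuilder(schema).fit(table.iloc[:300])
        X_test = builder.transform(table.iloc[300:])
        mu, sd = builder.stats_["age"]
        expected = (table.iloc[300:]["age"].to_numpy() - mu) / sd
        np.testing.assert_allclose(X_test["age"], expected)
        assert abs(X_test["age"].mean()) > 1e-6  # not re-centred on itself

    def test_drop_first_removes_reference_levels(self, complete_cohort):
        table = complete_cohort.table.set_index("patient_id")
        builder = g.DesignMatrixBuilder(complete_cohort.config.schema,
                                        drop_first=True).fit(table)
        X = builder.transform(table)
        assert "GCSm=1" not in X.columns and "GCSm=2" in X.columns

    def test_zero_training_sd_rejected(self):
        schema = [g.PredictorSpec("x", "continuous",
                                  dist={"family": "normal", "mean": 0, "sd": 1})]
        df = pd.DataFrame({"x": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="zero training SD"):
            g.DesignMatrixBuilder(schema).fit(df)

    def test_incomplete_table_rejected(self, complete_cohort):
        table = complete_cohort.table.set_index("patient_id").copy()
        builder = g.DesignMatrixBuilder(complete_cohort.config.schema).fit(table)
        table.loc[table.index[0], "glucose"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            builder.transform(table)
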