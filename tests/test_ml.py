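import numpy as np
import pandas as pd
import pytest

from socmap import (SampleTable, partial_dependence, permutation_importance,
                    shap_decomposition, train_models)
from socmap.ml import adjusted_r2


def linear_table(n=160, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    frame = pd.DataFrame({
        "x": rng.uniform(0, 10, n), "y": rng.uniform(0, 10, n),
        "region": np.where(np.arange(n) % 2 == 0, "a", "b"),
        "soc": 10 + 2 * x1 + 1.0 + noise * rng.normal(size=n),
        "tn": x1, "tp": x2,
    })
    frame["soc"] -= frame["soc"].min() - 1.0  # keep soc positive
    return SampleTable(frame)


class TestTrainModels:
    def test_exact_linear_target_recovered_by_lr(self):
        table = linear_table()
        res = train_models(table, ["tn", "tp"], split_seed=0,
                           algorithms=("LR",))
        rep = res.reports[0]
        assert rep.test_adj_r2 >= 0.999
        assert rep.test_rmse <= 1e-6

    def test_split_is_70_30_stratified_and_reproducible(self):
        table = linear_table(n=200)
        res1 = train_models(table, ["tn", "tp"], split_seed=3,
                            algorithms=("LR",))
        res2 = train_models(table, ["tn", "tp"], split_seed=3,
                            algorithms=("LR",))
        np.testing.assert_array_equal(res1.train_index, res2.train_index)
        assert len(res1.test_index) == 60
        regions = table.frame["region"].to_numpy()
        share = (regions[res1.train_index] == "a").mean()
        assert share == pytest.approx(0.5, abs=0.02)
        assert not set(res1.train_index) & set(res1.test_index)

    def test_permuted_target_scores_near_zero(self, rng):
        table = linear_table(n=150, noise=0.1)
        frame = table.frame.copy()
        frame["soc"] = rng.permutation(frame["soc"].to_numpy())
        res = train_models(SampleTable(frame), ["tn", "tp"], split_seed=1,
                           algorithms=("LR", "RF"))
        for rep in res.reports:
            assert rep.test_adj_r2 <= 0.1

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            train_models(linear_table(n=40), ["tn"], 0)

    def test_scaler_fitted_on_training_rows_only(self):
        table = linear_table(n=160)
        res = train_models(table, ["tn", "tp"], split_seed=0,
                           algorithms=("LR",))
        scaler = res.estimators["LR"].named_steps["scale"]
        np.testing.assert_allclose(
            scaler.mean_, res.X_train.mean(axis=0), atol=1e-12)


class TestAdjustedR2:
    def test_formula(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        pred = y + np.array([0.1, -0.1, 0.1, -0.1, 0.1, -0.1])
        from sklearn.metrics import r2_score
        r2 = r2_score(y, pred)
        expected = 1 - (1 - r2) * 5 / (6 - 2 - 1)
        assert adjusted_r2(y, pred, 2) == pytest.approx(expected)


class TestPermutationImportance:
    def test_single_active_predictor_dominates(self, rng):
        X = rng.normal(size=(200, 3))
        y = 3 * X[:, 0]

        class Lin:
            def predict(self, Z):
                return 3 * Z[:, 0]

        table = permutation_importance(Lin(), X, y, ["a", "b", "c"], seed=0)
        top = table.iloc[0]
        assert top["predictor"] == "a"
        assert top["importance_pct"] > 99.0

    def test_exchangeable_predictors_split_importance(self, rng):
        X = rng.normal(size=(400, 2))
        y = X[:, 0] + X[:, 1]

        class Add:
            def predict(self, Z):
                return Z[:, 0] + Z[:, 1]

        table = permutation_importance(Add(), X, y, ["a", "b"], seed=0)
        assert abs(table["importance_pct"].iloc[0]
                   - table["importance_pct"].iloc[1]) < 10.0

    def test_constant_predictor_warns_and_zeroes(self, rng):
        X = np.column_stack([rng.normal(size=100), np.ones(100)])
        y = X[:, 0]

        class Lin:
            def predict(self, Z):
                return Z[:, 0]

        with pytest.warns(UserWarning, match="constant"):
            table = permutation_importance(Lin(), X, y, ["a", "const"],
                                           seed=0)
        row = table[table["predictor"] == "const"].iloc[0]
        assert row["importance_pct"] == 0.0


class TestPartialDependence:
    def test_additive_component_recovered_exactly(self, rng):
        X = rng.normal(size=(300, 3))

        class Model:
            def predict(self, Z):
                return 2.0 * Z[:, 0] + np.sin(Z[:, 1])

        pdp = partial_dependence(Model(), X, ["a", "b", "c"], "a")
        slope = np.polyfit(pdp.grid, pdp.response, 1)[0]
        assert slope == pytest.approx(2.0, abs=1e-6)
        resid = pdp.response - np.polyval(
            np.polyfit(pdp.grid, pdp.response, 1), pdp.grid)
        assert np.abs(resid).max() < 1e-6

    def test_ignored_predictor_gives_constant_curve(self, rng):
        X = rng.normal(size=(200, 2))

        class Model:
            def predict(self, Z):
                return Z[:, 0] ** 2

        pdp = partial_dependence(Model(), X, ["a", "b"], "b")
        assert np.ptp(pdp.response) < 1e-12

    def test_few_distinct_values_reduces_grid_with_warning(self, rng):
        X = np.column_stack([rng.integers(0, 3, 100).astype(float),
                             rng.normal(size=100)])

        class Model:
            def predict(self, Z):
                return Z[:, 0]

        with pytest.warns(UserWarning, match="distinct"):
            pdp = partial_dependence(Model(), X, ["a", "b"], "a")
        assert len(pdp.grid) == 3


class TestShapOnModels:
    def test_additivity_against_fitted_forest(self, rng):
        from sklearn.ensemble import RandomForestRegressor
        X = rng.normal(size=(150, 4))
        y = X[:, 0] + X[:, 1] * X[:, 2]
        rf = RandomForestRegressor(50, random_state=0, n_jobs=1).fit(X, y)
        dec = shap_decomposition(rf, X, list("abcd"), interactions=False,
                                 max_explain=60, seed=0)
        recon = dec.base_value + dec.values.sum(axis=1)
        np.testing.assert_allclose(recon, rf.predict(dec.X), atol=1e-6)
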