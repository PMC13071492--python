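"""Model fitting, metrics, selection, importance and partial
dependence, checked against hand oracles and constructed models."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_func_model, make_linear_model
from croplandn2o import mlcore, obsdata
from croplandn2o.errors import ConfigError, InputError
from croplandn2o.mlcore import Metrics, ModelSpec, evaluate, select_best


def _metrics_from(obs, pred):
    table = pd.DataFrame({"net_flux": obs})
    model = make_func_model(lambda cols: np.asarray(pred))
    # dummy predictors so the design matrix can be built
    for p in mlcore.PREDICTORS:
        table[p] = 0.0 if p != "crop" else "upland"
    return evaluate(model, table)


class TestMetrics:
    def test_hand_oracle(self):
        """obs (0,1,2), pred (0,1,4): RMSE=sqrt(4/3), MAE=2/3,
        R2 = 1 - 4/2 = -1."""
        m = _metrics_from([0.0, 1.0, 2.0], [0.0, 1.0, 4.0])
        assert m.rmse == pytest.approx(np.sqrt(4 / 3))
        assert m.mae == pytest.approx(2 / 3)
        assert m.r2 == pytest.approx(-1.0)

    def test_perfect_fit(self):
        m = _metrics_from([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert (m.r2, m.rmse, m.mae) == (1.0, 0.0, 0.0)

    def test_rmse_at_least_mae_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            obs = rng.normal(size=30)
            pred = obs + rng.normal(size=30)
            m = _metrics_from(obs, pred)
            assert m.rmse >= m.mae >= 0
            assert m.r2 <= 1

    def test_degenerate_test_sets_raise(self):
        with pytest.raises(InputError):
            _metrics_from([1.0], [1.0])
        with pytest.raises(InputError):
            _metrics_from([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_metrics_invariant_enforced(self):
        with pytest.raises(ValueError):
            Metrics(r2=0.5, rmse=0.1, mae=0.5, n_test=10)


class TestSelectBest:
    def _cand(self, family, r2, rmse=1.0, mae=0.5):
        model = make_linear_model({})
        model.family = family
        return model, Metrics(r2=r2, rmse=rmse, mae=mae, n_test=10)

    def test_highest_r2_wins(self):
        a = self._cand("boosted_trees", 0.77)
        b = self._cand("random_forest", 0.60)
        c = self._cand("generalized_linear", 0.55)
        assert select_best([b, a, c]) is a[0]

    def test_singleton(self):
        a = self._cand("random_forest", 0.3)
        assert select_best([a]) is a[0]

    def test_rmse_tie_break(self):
        a = self._cand("boosted_trees", 0.7, rmse=3.2)
        b = self._cand("random_forest", 0.7, rmse=3.5)
        assert select_best([b, a]) is a[0]

    def test_family_order_final_tie_break(self):
        a = self._cand("generalized_linear", 0.7)
        b = self._cand("boosted_trees", 0.7)
        assert select_best([a, b]) is a[0]

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            select_best([])


SMALL_GRID = {"learning_rate": [0.1], "max_depth": [3], "subsample": [0.75]}


class TestTuneAndFit:
    def test_constant_target(self, features_table):
        dev = features_table.copy()
        dev["net_flux"] = 2.5
        spec = ModelSpec("generalized_linear", cv_folds=3, seed=1)
        model = mlcore.tune_and_fit(dev, spec)
        np.testing.assert_allclose(model.predict(dev), 2.5, atol=1e-6)
        assert model.cv_rmse == pytest.approx(0.0, abs=1e-6)

    def test_determinism(self, features_table):
        spec = ModelSpec("boosted_trees", grid={"learning_rate": [0.05, 0.1],
                                                "max_depth": [2, 3],
                                                "subsample": [0.75]},
                         cv_folds=3, seed=9, n_estimators=50)
        m1 = mlcore.tune_and_fit(features_table, spec)
        m2 = mlcore.tune_and_fit(features_table, spec)
        assert m1.hyperparams == m2.hyperparams
        np.testing.assert_array_equal(m1.predict(features_table),
                                      m2.predict(features_table))

    def test_row_order_independence(self, features_table):
        spec = ModelSpec("generalized_linear", cv_folds=3, seed=1)
        model = mlcore.tune_and_fit(features_table, spec)
        shuffled = features_table.sample(frac=1.0, random_state=4)
        np.testing.assert_allclose(
            model.predict(shuffled),
            model.predict(features_table)[shuffled.index.to_numpy()],
            rtol=1e-10)

    def test_too_few_rows_rejected(self, features_table):
        spec = ModelSpec("generalized_linear", cv_folds=30, seed=1)
        with pytest.raises(ConfigError):
            mlcore.tune_and_fit(features_table.head(20), spec)

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError):
            ModelSpec("deep_net").validate()


class TestImportance:
    def test_normalization_sums_to_100(self, features_table):
        spec = ModelSpec("boosted_trees", grid=SMALL_GRID, cv_folds=2,
                         seed=2, n_estimators=100)
        model = mlcore.tune_and_fit(features_table, spec)
        imp = mlcore.relative_importance(model)
        assert imp.sum() == pytest.approx(100.0, abs=1e-6)
        assert (imp >= 0).all()

    def test_irrelevant_feature_near_zero(self, features_table):
        """The surface never uses BD, so its influence is ~0."""
        spec = ModelSpec("boosted_trees", grid=SMALL_GRID, cv_folds=2,
                         seed=2, n_estimators=100)
        model = mlcore.tune_and_fit(features_table, spec)
        imp = mlcore.relative_importance(model)
        assert imp["BD"] < 2.0

    def test_permutation_fallback_for_glm(self, features_table):
        spec = ModelSpec("generalized_linear", cv_folds=3, seed=1)
        model = mlcore.tune_and_fit(features_table, spec)
        imp = mlcore.relative_importance(model, features_table, seed=0)
        assert imp.sum() == pytest.approx(100.0, abs=1e-6)

    def test_invariant_under_feature_reordering(self, features_table):
        spec = ModelSpec("boosted_trees", grid=SMALL_GRID, cv_folds=2,
                         seed=2, n_estimators=100)
        model = mlcore.tune_and_fit(features_table, spec)
        imp1 = mlcore.relative_importance(model)
        reordered = features_table[list(reversed(features_table.columns))]
        model2 = mlcore.tune_and_fit(reordered, spec)
        imp2 = mlcore.relative_importance(model2)
        pd.testing.assert_series_equal(imp1, imp2)


class TestPartialDependence:
    def test_flat_for_ignored_variable(self, features_table):
        model = make_linear_model({"MAT": 2.0}, intercept=1.0)
        curve = mlcore.partial_dependence(model, features_table, "BD")
        assert curve.is_flat

    def test_linear_slope_recovered_exactly(self, features_table):
        """PD of a model linear in x has slope equal to the model
        coefficient (least-squares oracle on the raw curve)."""
        beta = 1.7
        model = make_linear_model({"SOM": beta}, intercept=0.3)
        curve = mlcore.partial_dependence(model, features_table, "SOM")
        slope = np.polyfit(curve.grid, curve.raw, 1)[0]
        assert slope == pytest.approx(beta, rel=1e-9)

    def test_fitted_slope_within_ci_of_truth(self, features_table):
        """A GLM fitted to a noiseless linear target recovers the PDP
        slope of the generating coefficient."""
        beta = 0.8
        dev = features_table.copy()
        dev["net_flux"] = beta * dev["MAT"].to_numpy()
        spec = ModelSpec("generalized_linear", grid={"alpha": [1e-8]},
                         cv_folds=3, seed=1)
        model = mlcore.tune_and_fit(dev, spec)
        curve = mlcore.partial_dependence(model, dev, "MAT")
        slope = np.polyfit(curve.grid, curve.raw, 1)[0]
        assert slope == pytest.approx(beta, rel=1e-4)

    def test_additive_model_pd_matches_component(self, features_table):
        """PD of an additive model equals its component function up to
        a constant."""
        model = make_func_model(
            lambda c: np.sin(c["pH"]) + 0.01 * c["AAP"])
        grid = np.linspace(4.5, 8.5, 30)
        curve = mlcore.partial_dependence(model, features_table, "pH", grid=grid)
        centered = curve.raw - curve.raw.mean()
        expected = np.sin(grid) - np.sin(grid).mean()
        np.testing.assert_allclose(centered, expected, atol=1e-9)

    def test_loess_preserves_linear_input(self, features_table):
        model = make_linear_model({"TN": 3.0})
        curve = mlcore.partial_dependence(model, features_table, "TN",
                                          loess_span=1.0)
        np.testing.assert_allclose(curve.smoothed, curve.raw, atol=1e-6)

    def test_extrapolation_flagged(self, features_table):
        model = make_linear_model({"MAT": 1.0})
        grid = np.linspace(-50, 60, 12)
        with pytest.warns(UserWarning):
            curve = mlcore.partial_dependence(model, features_table, "MAT",
                                              grid=grid)
        assert curve.extrapolated

    def test_unknown_variable_rejected(self, features_table):
        model = make_linear_model({})
        with pytest.raises(InputError):
            mlcore.partial_dependence(model, features_table, "SWC")


class TestFamilyComparison:
    def test_boosted_beats_glm_on_nonlinear_surface(self, noiseless_config):
        """The surface is nonlinear with interactions, so boosted trees
        should outperform the linear family out of sample."""
        from croplandn2o import synthgen
        table, _ = synthgen.generate_observation_table(n=1200, seed=21)
        table, _ = obsdata.screen_records(table)
        table = obsdata.derive_features(table)
        dev, test = obsdata.split_dev_test(table, 0.9, seed=22)
        brt = mlcore.tune_and_fit(dev, ModelSpec(
            "boosted_trees", grid=SMALL_GRID, cv_folds=3, seed=23))
        glm = mlcore.tune_and_fit(dev, ModelSpec(
            "generalized_linear", cv_folds=3, seed=23))
        m_brt, m_glm = evaluate(brt, test), evaluate(glm, test)
        assert m_brt.rmse < m_glm.rmse
        assert select_best([(glm, m_glm), (brt, m_brt)]).family == "boosted_trees"
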