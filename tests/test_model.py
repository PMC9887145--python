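import numpy as np
import pandas as pd
import pytest

from uavyield.errors import ModelError
from uavyield.model import (
    EvalReport,
    ModelConfig,
    compare_feature_sets,
    evaluate,
    fit_and_evaluate,
    regression_metrics,
    residual_vs_lodging,
    split_train_test,
    train_rfr,
    variable_importance,
)
from uavyield.synthetic import ScenarioConfig, make_feature_table


@pytest.fixture(scope="module")
def table():
    return make_feature_table(ScenarioConfig(), seed=42)


class TestSplit:
    def test_132_rows_split_106_26(self, table):
        train, test = split_train_test(table, ModelConfig())
        assert (len(train), len(test)) == (106, 26)
        assert set(train.plot_id).isdisjoint(test.plot_id)
        assert len(train) + len(test) == len(table)

    def test_same_seed_same_membership(self, table):
        a = split_train_test(table, ModelConfig(rng_seed=15))
        b = split_train_test(table, ModelConfig(rng_seed=15))
        assert list(a[0].plot_id) == list(b[0].plot_id)

    def test_full_fraction_rejected(self):
        with pytest.raises(ModelError):
            ModelConfig(train_fraction=1.0)

    def test_too_few_rows_rejected(self, table):
        with pytest.raises(ModelError, match="at least 10"):
            split_train_test(table.head(5), ModelConfig())


class TestMetricsOracle:
    def test_three_point_hand_computation(self):
        r2, rmse, rrmse = regression_metrics([2, 4, 6], [3, 3, 6])
        assert r2 == pytest.approx(0.75)
        assert rmse == pytest.approx(np.sqrt(2 / 3), abs=1e-4)
        assert rrmse == pytest.approx(20.41, abs=0.01)

    def test_perfect_predictions(self):
        assert regression_metrics([2, 4, 6], [2, 4, 6]) == pytest.approx((1.0, 0.0, 0.0))

    def test_mean_predictor_gives_zero_r2(self):
        r2, _, _ = regression_metrics([2, 4, 6], [4, 4, 4])
        assert r2 == pytest.approx(0.0)

    def test_zero_variance_observations_r2_undefined(self):
        r2, rmse, _ = regression_metrics([5, 5, 5], [5, 6, 5])
        assert np.isnan(r2) and rmse > 0

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_agrees_with_direct_formulas_on_short_vectors(self, n):
        rng = np.random.default_rng(n)
        obs, pred = rng.uniform(1, 10, n), rng.uniform(1, 10, n)
        r2, rmse, rrmse = regression_metrics(obs, pred)
        ss_res = sum((p - o) ** 2 for o, p in zip(obs, pred))
        ss_tot = sum((o - obs.mean()) ** 2 for o in obs)
        assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)
        assert rmse == pytest.approx((ss_res / n) ** 0.5, abs=1e-12)
        assert rrmse == pytest.approx(rmse / obs.mean() * 100, abs=1e-12)

    def test_row_order_invariance_and_unit_scaling(self):
        rng = np.random.default_rng(9)
        obs, pred = rng.uniform(2000, 12000, 30), rng.uniform(2000, 12000, 30)
        perm = rng.permutation(30)
        assert regression_metrics(obs, pred) == pytest.approx(
            regression_metrics(obs[perm], pred[perm])
        )
        r2a, rmsea, rrmsea = regression_metrics(obs, pred)
        r2b, rmseb, rrmseb = regression_metrics(obs / 1000, pred / 1000)
        assert r2b == pytest.approx(r2a)
        assert rmseb == pytest.approx(rmsea / 1000)
        assert rrmseb == pytest.approx(rrmsea)


class TestRandomForest:
    def test_constant_target_predicts_constant(self, table):
        t = table.copy()
        t["yield_kg_ha"] = 7000.0
        cfg = ModelConfig()
        train, test = split_train_test(t, cfg)
        model = train_rfr(train, cfg)
        assert np.allclose(model.predict(test[model.feature_names_].to_numpy()), 7000.0)

    def test_same_seed_bit_identical_predictions(self, table):
        cfg = ModelConfig(rng_seed=15)
        preds = []
        for _ in range(2):
            train, test = split_train_test(table, cfg)
            model = train_rfr(train, cfg)
            preds.append(model.predict(test[model.feature_names_].to_numpy()))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_missing_values_rejected(self, table):
        t = table.copy()
        t.loc[t.index[0], "NDVI"] = np.nan
        with pytest.raises(ModelError, match="missing"):
            train_rfr(t, ModelConfig())

    def test_with_li_features_include_li(self, table):
        cfg = ModelConfig()
        train, _ = split_train_test(table, cfg)
        with_li = train_rfr(train, ModelConfig(feature_set="with_LI"))
        without = train_rfr(train, ModelConfig(feature_set="without_LI"))
        assert "LI" in with_li.feature_names_
        assert "LI" not in without.feature_names_


class TestImportance:
    def test_importances_normalised(self, table):
        rep = fit_and_evaluate(table, ModelConfig())
        assert rep.importances.importance.sum() == pytest.approx(1.0, abs=1e-9)
        assert (rep.importances.importance >= 0).all()

    def test_single_feature_gets_all_importance(self, table):
        cfg = ModelConfig(feature_set="without_LI")
        train, _ = split_train_test(table, cfg)
        model = train_rfr(train, cfg, features=["NDVI"])
        imp = variable_importance(model)
        assert imp.loc[0, "importance"] == pytest.approx(1.0)

    def test_noise_feature_ranks_below_generative_features(self):
        wins = 0
        for seed in range(20):
            t = make_feature_table(ScenarioConfig(), seed=seed)
            t["pure_noise"] = np.random.default_rng(seed + 1000).normal(size=len(t))
            rep = fit_and_evaluate(t, ModelConfig(rng_seed=seed))
            ranked = list(rep.importances.feature)
            # generative drivers: vigor enters via NDVI & CH; lodging via LI
            if ranked.index("pure_noise") > max(
                ranked.index("NDVI"), ranked.index("CH"), ranked.index("LI")
            ):
                wins += 1
        assert wins >= 16


class TestResidualVsLodging:
    def test_zero_residuals_zero_slope(self):
        rep = EvalReport(
            pd.DataFrame(
                {"plot_id": ["A", "B", "C"], "observed": [1.0, 2, 3], "predicted": [1.0, 2, 3], "residual": [0.0, 0, 0]}
            ),
            1.0, 0.0, 0.0, pd.DataFrame({"feature": [], "importance": []}),
        )
        lodging = pd.DataFrame({"plot_id": ["A", "B", "C"], "LI": [0.0, 0.5, 1.5]})
        trend = residual_vs_lodging(rep, lodging)
        assert trend.slope == pytest.approx(0.0, abs=1e-12)
        assert trend.tercile_counts.n_over.sum() == 0
        assert trend.tercile_counts.n_under.sum() == 0

    def test_join_failure_names_plots(self):
        rep = EvalReport(
            pd.DataFrame({"plot_id": ["A", "Z"], "observed": [1.0, 2], "predicted": [1.0, 2], "residual": [0.0, 0]}),
            1.0, 0.0, 0.0, pd.DataFrame(),
        )
        lodging = pd.DataFrame({"plot_id": ["A"], "LI": [0.0]})
        with pytest.raises(ModelError, match="Z"):
            residual_vs_lodging(rep, lodging)


class TestLodgingIndexValue:
    """Simulation checks: the lodging penalty is learnable only through LI."""

    def test_with_li_usually_beats_without(self):
        wins = 0
        for seed in range(10):
            t = make_feature_table(ScenarioConfig(), seed=seed)
            reports = compare_feature_sets(t, ModelConfig(rng_seed=seed))
            if reports["with_LI"].rmse <= reports["without_LI"].rmse:
                wins += 1
        assert wins >= 7

    def test_no_spurious_gain_without_lodging_penalty(self):
        diffs = []
        for seed in range(10):
            t = make_feature_table(ScenarioConfig(lodging_penalty=0.0), seed=seed)
            reports = compare_feature_sets(t, ModelConfig(rng_seed=seed))
            diffs.append(reports["without_LI"].rmse - reports["with_LI"].rmse)
        wins = sum(d > 0 for d in diffs)
        assert 1 <= wins <= 9  # neither direction dominates

    def test_test_r2_improves_as_noise_shrinks(self):
        r2s = []
        for noise in (2000.0, 500.0, 100.0):
            vals = []
            for seed in range(5):
                t = make_feature_table(ScenarioConfig(yield_noise_sd=noise), seed=seed)
                vals.append(fit_and_evaluate(t, ModelConfig(rng_seed=seed)).r2)
            r2s.append(np.mean(vals))
        assert r2s[0] < r2s[1] < r2s[2]
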