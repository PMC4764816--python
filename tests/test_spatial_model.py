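import numpy as np
import pandas as pd
import pytest

from soc3d.spatial_model import (
    RFConfig, predict_parameters, repeat_oob, train_mattic_classifier,
    train_model_set, train_param_regressor, variable_importance,
)

FAST = RFConfig(ntree=300, seed=0)


def _classification_table(n=200, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    ndvi = rng.uniform(-0.2, 0.9, n)
    noise1 = rng.normal(size=n)
    noise2 = rng.normal(size=n)
    label = ndvi > 0.35 if separable else rng.random(n) < 0.5
    return pd.DataFrame({
        "NDVI": ndvi, "x1": noise1, "x2": noise2, "has_mattic": label,
    })


def _regression_table(n=500, seed=0, informative=True, noise_sd=0.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n)
    z = rng.normal(size=n)
    y = (2.0 + 3.0 * x if informative else np.full(n, 2.0))
    y = np.exp(y * 0.3 + rng.normal(0, noise_sd, n))
    return pd.DataFrame({"x": x, "z": z, "target": y,
                         "site_id": [f"s{i}" for i in range(n)]})


class TestClassifier:
    def test_separable_data_low_oob_error(self):
        table = _classification_table(separable=True)
        _, err = train_mattic_classifier(table, ["NDVI", "x1", "x2"], FAST)
        assert err < 0.05

    def test_permuted_labels_near_baseline(self):
        table = _classification_table(separable=False, seed=1)
        _, err = train_mattic_classifier(table, ["NDVI", "x1", "x2"], FAST)
        baseline = min(table["has_mattic"].mean(), 1 - table["has_mattic"].mean())
        assert err == pytest.approx(baseline, abs=0.1)

    def test_single_class_rejected(self):
        table = _classification_table()
        table["has_mattic"] = True
        with pytest.raises(ValueError):
            train_mattic_classifier(table, ["NDVI", "x1", "x2"], FAST)


class TestRegressor:
    def test_strong_signal_small_oob_mse(self):
        table = _regression_table(informative=True)
        _, mse = train_param_regressor(table, ["x", "z"], "target", FAST)
        var = np.var(np.log(table["target"]))
        assert mse < 0.05 * var

    def test_uninformative_covariates_mse_near_variance(self):
        # single realizations fluctuate; the mean ratio over a few draws
        # must sit near 1 (full-depth trees would inflate it to ~1.2)
        ratios = []
        for seed in (2, 3, 4):
            table = _regression_table(informative=False, noise_sd=0.5, seed=seed)
            _, mse = train_param_regressor(table, ["x", "z"], "target", FAST)
            ratios.append(mse / np.var(np.log(table["target"])))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_constant_target_zero_mse(self):
        table = _regression_table(informative=False, noise_sd=0.0)
        _, mse = train_param_regressor(table, ["x", "z"], "target", FAST)
        assert mse == pytest.approx(0.0, abs=1e-12)

    def test_non_positive_target_names_site(self):
        table = _regression_table(n=30)
        table.loc[7, "target"] = 0.0
        with pytest.raises(ValueError, match="s7"):
            train_param_regressor(table, ["x", "z"], "target", FAST)


class TestRepeatOOB:
    def test_summary_statistics_ordered(self):
        table = _classification_table(n=120, seed=3)

        def trainer(seed):
            _, err = train_mattic_classifier(
                table, ["NDVI", "x1", "x2"], RFConfig(ntree=100), seed=seed
            )
            return err

        s = repeat_oob(trainer, RFConfig(ntree=100, n_runs=10, seed=0))
        assert s["minimum"] <= s["q1"] <= s["median"] <= s["q3"] <= s["maximum"]
        assert s["minimum"] <= s["mean"] <= s["maximum"]
        assert s["sd"] >= 0

    def test_identical_seeds_zero_sd(self):
        table = _classification_table(n=80, seed=4)

        def trainer(_seed):
            _, err = train_mattic_classifier(
                table, ["NDVI", "x1", "x2"], RFConfig(ntree=50), seed=123
            )
            return err

        s = repeat_oob(trainer, RFConfig(n_runs=3, seed=0))
        assert s["sd"] == 0.0

    def test_row_order_invariance(self):
        table = _classification_table(n=100, seed=5)
        shuffled = table.sample(frac=1.0, random_state=9).reset_index(drop=True)

        def make(t):
            def trainer(seed):
                _, err = train_mattic_classifier(
                    t, ["NDVI", "x1", "x2"], RFConfig(ntree=100), seed=seed
                )
                return err
            return repeat_oob(trainer, RFConfig(ntree=100, n_runs=5, seed=0))

        a, b = make(table), make(shuffled)
        # same OOB error distribution within run-to-run spread
        assert a["mean"] == pytest.approx(b["mean"], abs=3 * (a["sd"] + b["sd"] + 0.01))


class TestOOBReconstruction:
    def test_matches_sklearn_oob_predictions(self):
        # the per-tree bootstrap reconstruction used for OOB-permutation
        # importance must agree with the forest's own OOB aggregation
        table = _regression_table(n=200, seed=42, informative=True,
                                  noise_sd=0.3)
        model, _ = train_param_regressor(table, ["x", "z"], "target",
                                         RFConfig(ntree=100), seed=3)
        from soc3d.spatial_model import oob_predictions

        X = table[["x", "z"]].to_numpy()
        mine = oob_predictions(model, X)
        ref = model.oob_prediction_
        ok = ~np.isnan(mine)
        assert np.allclose(mine[ok], ref[ok])


class TestImportance:
    def test_generative_beats_noise_in_seeded_repeats(self):
        wins = 0
        for rep in range(20):
            table = _regression_table(n=200, seed=100 + rep, informative=True,
                                      noise_sd=0.1)
            model, _ = train_param_regressor(
                table, ["x", "z"], "target", RFConfig(ntree=200), seed=rep
            )
            imp = variable_importance(
                model, table, ["x", "z"], "target", RFConfig(ntree=200, seed=rep)
            )
            wins += imp.iloc[0]["covariate"] == "x"
        assert wins >= 19  # >= 95% of 20 repeats

    def test_all_noise_importance_near_zero(self):
        table = _regression_table(n=300, seed=6, informative=False, noise_sd=0.5)
        model, _ = train_param_regressor(table, ["x", "z"], "target", FAST)
        imp = variable_importance(model, table, ["x", "z"], "target", FAST)
        var = np.var(np.log(table["target"]))
        assert (imp["importance"].abs() < 0.35 * var).all()

    def test_single_covariate_carries_all_mass(self):
        table = _regression_table(n=200, seed=7, informative=True, noise_sd=0.05)
        model, _ = train_param_regressor(table, ["x"], "target", FAST)
        imp = variable_importance(model, table, ["x"], "target", FAST)
        assert len(imp) == 1 and imp.iloc[0]["importance"] > 0


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(8)
    n = 150
    ndvi = rng.uniform(0, 1, n)
    mat = rng.normal(size=n)
    has = ndvi > 0.45
    table = pd.DataFrame({
        "NDVI": ndvi, "MAT": mat, "has_mattic": has,
        "d_mat": np.where(has, 0.1 + 0.1 * ndvi, np.nan),
        "c_a": np.exp(3.0 + 0.5 * ndvi),
        "k": np.exp(0.8 + 0.2 * mat),
        "site_id": [f"s{i}" for i in range(n)],
    })
    models = train_model_set(table, ["NDVI", "MAT"],
                             RFConfig(ntree=200, seed=1))
    return models, table


class TestModelSetPrediction:
    def test_positive_parameters_everywhere(self, trained):
        models, table = trained
        params = predict_parameters(models, table)
        for p in params:
            assert p is not None and p.c_a > 0 and p.k > 0
            assert (p.d_mat > 0) == p.has_mattic

    def test_in_bag_recovery(self, trained):
        models, table = trained
        params = predict_parameters(models, table)
        pred_log_ca = np.log([p.c_a for p in params])
        true_log_ca = np.log(table["c_a"].to_numpy())
        r = np.corrcoef(pred_log_ca, true_log_ca)[0, 1]
        assert r > 0.9  # forests memorize their training rows

    def test_nodata_row_skipped(self, trained):
        models, table = trained
        rows = table.head(3).copy()
        rows.loc[rows.index[1], "NDVI"] = np.nan
        params = predict_parameters(models, rows)
        assert params[1] is None and params[0] is not None

    def test_missing_covariate_rejected(self, trained):
        models, table = trained
        with pytest.raises(ValueError):
            predict_parameters(models, table.drop(columns="MAT"))

    def test_seeded_training_bit_reproducible(self, trained):
        _, table = trained
        m1 = train_model_set(table, ["NDVI", "MAT"], RFConfig(ntree=100, seed=5))
        m2 = train_model_set(table, ["NDVI", "MAT"], RFConfig(ntree=100, seed=5))
        p1 = predict_parameters(m1, table)
        p2 = predict_parameters(m2, table)
        assert p1 == p2
        assert m1.oob == m2.oob

    def test_save_load_round_trip(self, trained, tmp_path):
        models, table = trained
        models.save(tmp_path / "models")
        from soc3d.spatial_model import TrainedModelSet

        back = TrainedModelSet.load(tmp_path / "models")
        assert back.covariates == models.covariates
        assert predict_parameters(back, table) == predict_parameters(models, table)
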