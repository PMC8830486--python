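"""Correlation screen and LOSOCV ensembles."""

import numpy as np
import pandas as pd
import pytest

from neoprog.inference import (
    ModelSpec,
    fit_ensemble,
    losocv,
    p_from_r,
    pearson_r,
    regression_metrics,
    screen_features,
)


class TestPearsonR:
    def test_perfect_lines(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1) == 1.0
        assert pearson_r(x, -x) == -1.0

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_r(x, y) == pytest.approx(num / den, abs=1e-15)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r(np.ones(5), np.arange(5.0))


class TestPFromR:
    @pytest.mark.parametrize("r,expected", [(-0.46, 0.04), (0.48, 0.03)])
    def test_worked_examples_round_to_printed_values(self, r, expected):
        assert round(p_from_r(r, 20), 2) == expected

    def test_zero_correlation_gives_p_one(self):
        assert p_from_r(0.0, 20) == 1.0

    def test_perfect_correlation_gives_p_zero(self):
        assert p_from_r(1.0, 10) == 0.0
        assert p_from_r(-1.0, 10) == 0.0

    def test_sign_symmetric(self):
        assert p_from_r(0.37, 20) == pytest.approx(p_from_r(-0.37, 20), abs=1e-15)

    def test_matches_permutation_null_at_n_20(self):
        """The t-based p-value should agree with a large Monte-Carlo
        permutation p-value within 0.01 for moderate correlations."""
        rng = np.random.default_rng(0)
        n = 20
        x = rng.standard_normal(n)
        y = 0.5 * (x - x.mean()) / x.std() + rng.standard_normal(n) * 0.9
        r_obs = pearson_r(x, y)
        xc = (x - x.mean()) / np.sqrt(np.sum((x - x.mean()) ** 2))
        count = 0
        total = 1_000_000
        chunk = 100_000
        for _ in range(total // chunk):
            perms = rng.permuted(np.tile(y, (chunk, 1)), axis=1)
            pc = perms - perms.mean(axis=1, keepdims=True)
            r_perm = (pc @ xc) / np.sqrt(np.sum(pc**2, axis=1))
            count += int(np.sum(np.abs(r_perm) >= abs(r_obs)))
        assert p_from_r(r_obs, n) == pytest.approx(count / total, abs=0.01)


class TestScreenFeatures:
    def test_planted_strong_feature_ranked_first(self):
        """A rho = 0.8 feature among 35 nulls should top the screen in at
        least 90% of 200 seeds at n = 20."""
        n = 20
        first = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal(n)
            scores = 0.8 * z + 0.6 * rng.standard_normal(n)
            table = pd.DataFrame(
                {"planted": z, **{f"null{i}": rng.standard_normal(n) for i in range(35)}}
            )
            result = screen_features(table, scores)
            first += result.iloc[0]["feature"] == "planted"
        assert first >= 0.90 * 200

    def test_threshold_is_inclusive(self):
        # build a feature whose p-value is exactly alpha by construction
        table = pd.DataFrame({"f": np.arange(6.0)})
        scores = np.array([0.0, 2.0, 1.0, 3.0, 2.5, 3.5])
        r = pearson_r(table["f"].to_numpy(), scores)
        alpha = p_from_r(r, 6)
        result = screen_features(table, scores, alpha=alpha)
        assert bool(result.iloc[0]["significant"])

    def test_results_sorted_by_p(self, rng):
        n = 20
        z = rng.standard_normal(n)
        table = pd.DataFrame(
            {"a": rng.standard_normal(n), "b": z + 0.1 * rng.standard_normal(n)}
        )
        result = screen_features(table, z)
        assert list(result["p_value"]) == sorted(result["p_value"])

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="scores"):
            screen_features(pd.DataFrame({"a": np.arange(5.0)}), np.arange(4.0))


class TestEnsembles:
    def test_deep_trees_interpolate_step_function(self):
        x = np.repeat([0.0, 1.0, 2.0, 3.0], 5)[:, None]
        y = np.repeat([10.0, 20.0, 30.0, 40.0], 5)
        model = fit_ensemble(x, y, ModelSpec(kind="boosted", n_learners=100,
                                             learning_rate=1.0, min_leaf=1))
        assert np.allclose(model.predict(x), y, atol=1e-6)

    def test_boosted_single_learner_unit_rate_is_one_tree(self, rng):
        from sklearn.tree import DecisionTreeRegressor

        x = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        spec = ModelSpec(kind="boosted", n_learners=1, learning_rate=1.0,
                         min_leaf=4, max_depth=3, seed=0)
        ens = fit_ensemble(x, y, spec)
        tree = DecisionTreeRegressor(min_samples_leaf=4, max_depth=3, random_state=0)
        tree.fit(x, y - y.mean())
        assert np.allclose(ens.predict(x), y.mean() + tree.predict(x), atol=1e-10)

    def test_bagged_prediction_is_mean_of_learners(self, rng):
        x = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        model = fit_ensemble(x, y, ModelSpec(kind="bagged", seed=1))
        individual = np.mean([est.predict(x) for est in model.estimators_], axis=0)
        assert np.allclose(model.predict(x), individual, atol=1e-12)

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        p1 = fit_ensemble(x, y, ModelSpec(kind="bagged", seed=7)).predict(x)
        p2 = fit_ensemble(x, y, ModelSpec(kind="bagged", seed=7)).predict(x)
        assert np.array_equal(p1, p2)

    def test_non_finite_features_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit_ensemble(np.array([[1.0], [np.inf]]), np.array([1.0, 2.0]), ModelSpec())


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        assert regression_metrics(np.arange(5.0), np.arange(5.0)) == (0.0, 0.0, 1.0)

    def test_hand_computed_example(self):
        rmse, mae, r2 = regression_metrics(
            np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0])
        )
        assert rmse == pytest.approx(np.sqrt(2.0 / 3.0))
        assert mae == pytest.approx(2.0 / 3.0)
        assert r2 == pytest.approx(0.0)

    def test_translation_invariance_of_errors(self, rng):
        a = rng.standard_normal(10)
        p = rng.standard_normal(10)
        rmse1, mae1, _ = regression_metrics(a, p)
        rmse2, mae2, _ = regression_metrics(a + 5.0, p + 5.0)
        assert rmse1 == pytest.approx(rmse2)
        assert mae1 == pytest.approx(mae2)

    def test_zero_variance_actuals_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            regression_metrics(np.ones(4), np.arange(4.0))


class TestLosocv:
    def test_each_subject_predicted_once(self, rng):
        x = rng.standard_normal((20, 2))
        y = rng.standard_normal(20) * 10 + 100
        report = losocv(x, y, ModelSpec(kind="bagged", seed=0))
        assert len(report.predicted) == 20
        assert len([f for f in report.fold_log if f.get("fold") != "averaged"]) == 20

    def test_constant_scores_predicted_exactly(self, rng):
        x = rng.standard_normal((6, 1))
        y = np.full(6, 103.0)
        report = losocv(x, y, ModelSpec(kind="bagged", seed=0))
        assert report.rmse == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(report.r_squared)

    def test_signal_beats_shuffled_control(self):
        r2_signal, r2_null = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal(20)
            scores = 100 + 12.0 * z + 9.0 * rng.standard_normal(20)
            feats = z[:, None]
            r2_signal.append(losocv(feats, scores, ModelSpec(kind="boosted", seed=seed)).r_squared)
            shuffled = rng.permutation(scores)
            r2_null.append(losocv(feats, shuffled, ModelSpec(kind="boosted", seed=seed)).r_squared)
        assert np.median(r2_signal) > 0
        assert np.median(r2_null) <= 0.1

    def test_constant_model_baseline_never_positive(self, rng):
        """A mean-of-training-data predictor has held-out R^2 <= 0."""
        y = rng.standard_normal(15) * 10 + 100
        n = len(y)
        preds = np.array([np.delete(y, i).mean() for i in range(n)])
        _, _, r2 = regression_metrics(y, preds)
        assert r2 <= 0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            losocv(np.ones((2, 1)), np.array([1.0, 2.0]), ModelSpec())

    def test_end_to_end_determinism(self, rng):
        x = pd.DataFrame(rng.standard_normal((12, 3)))
        y = rng.standard_normal(12)
        r1 = losocv(x, y, ModelSpec(kind="boosted", seed=3))
        r2 = losocv(x, y, ModelSpec(kind="boosted", seed=3))
        assert np.array_equal(r1.predicted, r2.predicted)
        assert (r1.rmse, r1.mae, r1.r_squared) == (r2.rmse, r2.mae, r2.r_squared)
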