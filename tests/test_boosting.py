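"""Decision stumps, AdaBoost-M1 arithmetic, and gradient-boosting behaviour."""
from __future__ import annotations

import math

import numpy as np
import pytest

from hecasd.boosting import (
    AdaBoostM1,
    BoostingError,
    DecisionStump,
    RegularizedGradientBoosting,
    fit_adaboost,
    fit_gbm,
    fit_stump,
    load_model,
    log_loss,
    make_baseline,
    predict,
    save_model,
)


def brute_force_stump_error(X, y, w):
    """Oracle: scan every feature/threshold/polarity by direct counting."""
    best = math.inf
    n, d = X.shape
    for j in range(d):
        values = np.unique(X[:, j])
        thresholds = (values[:-1] + values[1:]) / 2
        for thr in thresholds:
            for left in (-1, 1):
                pred = np.where(X[:, j] <= thr, left, -left)
                best = min(best, float(w[pred != y].sum()))
    return best


class TestFitStump:
    def test_separable_midpoint(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([-1, -1, 1, 1])
        w = np.full(4, 0.25)
        stump, err = fit_stump(X, y, w)
        assert stump.threshold == 2.5
        assert err == 0.0
        assert np.array_equal(stump.predict(X), y)

    def test_one_versus_rest_split(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([-1, 1, 1, 1])
        stump, err = fit_stump(X, y, np.full(4, 0.25))
        assert stump.threshold == 0.5
        assert err == 0.0

    def test_doubling_weight_equals_duplicating_sample(self):
        rng = np.random.default_rng(31)
        X = rng.random((8, 3))
        y = np.where(rng.random(8) < 0.5, 1, -1)
        y[0], y[1] = 1, -1  # both classes present
        w = np.full(8, 1.0 / 9)
        w[2] = 2.0 / 9
        X_dup = np.vstack([X, X[2]])
        y_dup = np.append(y, y[2])
        _, err_weighted = fit_stump(X, y, w)
        _, err_dup = fit_stump(X_dup, y_dup, np.full(9, 1.0 / 9))
        assert err_weighted == pytest.approx(err_dup, abs=1e-12)

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            n = int(rng.integers(4, 20))
            X = rng.random((n, 3))
            y = np.where(rng.random(n) < 0.5, 1, -1)
            if np.unique(y).size < 2:
                continue
            w = rng.random(n)
            w /= w.sum()
            _, err = fit_stump(X, y, w)
            assert err == pytest.approx(brute_force_stump_error(X, y, w), abs=1e-12)

    def test_constant_features_majority_vote(self):
        X = np.ones((4, 2))
        y = np.array([1, 1, 1, -1])
        stump, err = fit_stump(X, y, np.full(4, 0.25))
        assert np.all(stump.predict(X) == 1)
        assert err == pytest.approx(0.25)


class TestAdaBoost:
    def test_zero_error_stop_on_separable_data(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([-1, -1, 1, 1])
        model = fit_adaboost(X, y, n_rounds=25)
        assert len(model.stumps) == 1
        assert model.errors_ == [0.0]
        assert np.array_equal(model.predict(X), y)

    def test_worked_round_arithmetic(self):
        # best stump (thr 1.5) misclassifies exactly the sample at x=0
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([1, -1, 1, 1])
        model = fit_adaboost(X, y, n_rounds=3)
        assert model.errors_[0] == pytest.approx(0.25)
        assert model.alphas[0] == pytest.approx(0.5 * math.log(3.0))
        w1 = model.weight_history_[1]
        misclassified = model.stumps[0].predict(X) != y
        assert w1[misclassified].sum() == pytest.approx(0.5, abs=1e-12)

    def test_weights_sum_to_one_and_move_the_right_way(self):
        rng = np.random.default_rng(41)
        X = rng.random((30, 4))
        y = np.where(X[:, 0] + 0.3 * rng.random(30) > 0.6, 1, -1)
        if np.unique(y).size < 2:
            pytest.skip("degenerate draw")
        model = fit_adaboost(X, y, n_rounds=10)
        for w in model.weight_history_:
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
        for m, stump in enumerate(model.stumps[:-1]):
            before, after = model.weight_history_[m], model.weight_history_[m + 1]
            wrong = stump.predict(X) != y
            if model.errors_[m] == 0.0:
                continue
            assert np.all(after[wrong] > before[wrong])
            assert np.all(after[~wrong] < before[~wrong])

    def test_training_error_bound(self):
        """0/1 training error <= prod 2 sqrt(eps (1 - eps))."""
        rng = np.random.default_rng(43)
        X = rng.random((40, 3))
        y = np.where(X[:, 1] > 0.5, 1, -1)
        X[:5] += 0.2 * rng.random((5, 3))  # mild noise
        model = fit_adaboost(X, y, n_rounds=15)
        pred = model.predict(X)
        bound = np.prod([2 * math.sqrt(e * (1 - e)) for e in model.errors_ if e > 0])
        assert np.mean(pred != y) <= bound + 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(BoostingError):
            fit_adaboost(np.random.rand(4, 2), np.ones(4), 5)

    def test_zero_one_label_convention(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y01 = np.array([0, 0, 1, 1])
        model = fit_adaboost(X, y01, 5)
        assert set(model.predict(X)) <= {0, 1}
        assert np.array_equal(model.predict(X), y01)

    def test_empty_ensemble_predicts_prior(self):
        X = np.array([[1.0], [2.0], [3.0]])
        model = AdaBoostM1(n_rounds=0)
        model.fit(np.array([[1.0], [2.0], [3.0], [4.0]]), np.array([0, 1, 1, 1]))
        assert np.all(model.predict(X) == 1)

    def test_serialization_round_trip(self, tmp_path):
        X = np.random.default_rng(3).random((20, 3))
        y = np.where(X[:, 0] > 0.5, 1, 0)
        model = fit_adaboost(X, y, 8)
        path = tmp_path / "ada.json"
        save_model(model, str(path))
        reloaded = load_model(str(path))
        assert np.array_equal(reloaded.predict(X), model.predict(X))
        assert np.allclose(
            reloaded.decision_function(X), model.decision_function(X)
        )


class TestLogLoss:
    def test_hand_value(self):
        assert log_loss([1, 0], [0.9, 0.1]) == pytest.approx(
            -math.log(0.9), abs=1e-9
        )

    def test_uninformative_predictor(self):
        assert log_loss([1, 0, 1], [0.5, 0.5, 0.5]) == pytest.approx(math.log(2))

    def test_perfect_prediction_limit(self):
        assert log_loss([1, 0], [1.0, 0.0]) == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(BoostingError):
            log_loss([1, 0], [0.5])


def two_moons(n, seed):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 4))
    y = ((X[:, 0] + X[:, 1] + 0.2 * rng.standard_normal(n)) > 1.0).astype(int)
    return X, y


class TestGradientBoosting:
    def test_training_loss_monotone(self):
        X, y = two_moons(80, 47)
        model = fit_gbm(X, y, {"n_trees": 60, "learning_rate": 0.1})
        losses = model.train_loss_
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_huge_lambda_collapses_to_prior(self):
        X, y = two_moons(50, 53)
        model = fit_gbm(X, y, {"n_trees": 20, "lambda_l2": 1e9})
        prior = 1.0 / (1.0 + math.exp(-model.base_score))
        assert model.predict_proba(X) == pytest.approx(
            np.full(len(y), prior), abs=1e-6
        )

    def test_first_split_matches_exhaustive_search(self):
        """Depth-1, lambda=0: the first tree picks the best least-squares split."""
        rng = np.random.default_rng(59)
        X = rng.random((40, 1))
        y = (X[:, 0] > 0.6).astype(int)
        model = RegularizedGradientBoosting(
            n_trees=1, learning_rate=0.1, max_depth=1, lambda_l2=0.0
        ).fit(X, y)
        tree = model.trees[0]
        # oracle: residuals after the constant fit, best SSE split
        resid = y - y.mean()
        xs = np.sort(np.unique(X[:, 0]))
        best_thr, best_sse = None, math.inf
        for thr in (xs[:-1] + xs[1:]) / 2:
            left = X[:, 0] <= thr
            sse = ((resid[left] - resid[left].mean()) ** 2).sum() + (
                (resid[~left] - resid[~left].mean()) ** 2
            ).sum()
            if sse < best_sse - 1e-15:
                best_thr, best_sse = thr, sse
        assert tree.feature_index == 0
        assert tree.threshold == pytest.approx(best_thr, abs=1e-12)

    def test_max_depth_respected(self):
        X, y = two_moons(60, 61)
        model = fit_gbm(X, y, {"n_trees": 10, "max_depth": 2})

        def depth(node):
            if node.feature_index is None:
                return 0
            return 1 + max(depth(node.left), depth(node.right))

        assert all(depth(t) <= 2 for t in model.trees)

    def test_single_class_degenerates_to_prior(self, caplog):
        X = np.random.default_rng(67).random((10, 2))
        model = fit_gbm(X, np.ones(10, dtype=int), {"n_trees": 5})
        assert model.trees == []
        assert np.all(model.predict(X) == 1)

    def test_empty_ensemble_predicts_base_score(self):
        X, y = two_moons(30, 71)
        model = fit_gbm(X, y, {"n_trees": 0})
        assert np.allclose(model.raw_score(X), model.base_score)

    def test_bit_reproducible(self):
        X, y = two_moons(50, 73)
        p1 = fit_gbm(X, y, {"n_trees": 20}).predict_proba(X)
        p2 = fit_gbm(X, y, {"n_trees": 20}).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_serialization_round_trip(self, tmp_path):
        X, y = two_moons(40, 79)
        model = fit_gbm(X, y, {"n_trees": 15})
        path = tmp_path / "gbm.json"
        save_model(model, str(path))
        reloaded = load_model(str(path))
        assert np.allclose(reloaded.predict_proba(X), model.predict_proba(X))

    def test_dimension_mismatch_rejected(self):
        X, y = two_moons(30, 83)
        model = fit_gbm(X, y, {"n_trees": 2})
        with pytest.raises(BoostingError):
            model.predict(X[:, :2])


class TestUniformContract:
    @pytest.mark.parametrize("name", ["nb", "svm", "svm_rbf", "knn", "rf"])
    def test_baselines_fit_and_score(self, name):
        X, y = two_moons(60, 89)
        clf = make_baseline(name, seed=0).fit(X, y)
        labels, scores = predict(clf, X)
        assert labels.shape == scores.shape == y.shape
        assert set(np.unique(labels)) <= {0, 1}

    def test_prediction_invariant_to_sample_order(self):
        X, y = two_moons(40, 97)
        model = fit_gbm(X, y, {"n_trees": 10})
        perm = np.random.default_rng(1).permutation(len(X))
        assert np.array_equal(model.predict(X)[perm], model.predict(X[perm]))

    def test_unknown_baseline_rejected(self):
        with pytest.raises(BoostingError):
            make_baseline("mlp")
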