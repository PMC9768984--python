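"""Ensemble learners over decision stumps.

Two boosting schemes are implemented natively:

* **AdaBoost-M1** — sequential reweighting with exponential loss.  Each
  round fits the decision stump minimizing weighted 0/1 error, receives
  the vote ``alpha = 0.5 ln((1 - eps)/eps)``, and reweights samples by
  ``exp(-alpha * y * h(x))`` (misclassified samples gain weight).
  Training stops at the round budget or as soon as a stump is perfect.
* **Regularized gradient boosting** — an additive model of
  depth-limited regression trees fit to the gradients/hessians of the
  binomial log loss, with L2-penalized leaf values
  ``-sum(g) / (sum(h) + lambda)`` and a learning-rate-scaled update.

Baseline classifiers (naive Bayes, linear/RBF SVM, KNN, random forest)
are delegated to scikit-learn behind the same fit/predict contract.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "DecisionStump",
    "AdaBoostM1",
    "RegularizedGradientBoosting",
    "SklearnClassifier",
    "fit_stump",
    "fit_adaboost",
    "fit_gbm",
    "log_loss",
    "predict",
    "make_baseline",
    "BASELINES",
]

_ALPHA_CAP_EPS = 1e-10  # stands in for eps=0 so alpha stays finite


class BoostingError(ValueError):
    """Raised for invalid training inputs or model misuse."""


# ---------------------------------------------------------------------------
# label handling


def to_signed(y: np.ndarray) -> np.ndarray:
    """Map 0/1 (or already signed) labels to -1/+1."""
    y = np.asarray(y)
    uniq = set(np.unique(y).tolist())
    if uniq <= {-1, 1}:
        return y.astype(int)
    if uniq <= {0, 1}:
        return np.where(y > 0, 1, -1)
    raise BoostingError(f"labels must be binary 0/1 or -1/+1, got {sorted(uniq)}")


def to_binary(y: np.ndarray) -> np.ndarray:
    """Map -1/+1 (or already 0/1) labels to 0/1."""
    y = np.asarray(y)
    uniq = set(np.unique(y).tolist())
    if uniq <= {0, 1}:
        return y.astype(int)
    if uniq <= {-1, 1}:
        return np.where(y > 0, 1, 0)
    raise BoostingError(f"labels must be binary 0/1 or -1/+1, got {sorted(uniq)}")


def log_loss(y: Sequence[float], p: Sequence[float]) -> float:
    """Mean binomial deviance: -(1/N) sum[y ln p + (1-y) ln(1-p)].

    Probabilities are clipped to [1e-15, 1 - 1e-15] before the logs.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise BoostingError(f"length mismatch: {y.shape} labels vs {p.shape} probabilities")
    p = np.clip(p, 1e-15, 1.0 - 1e-15)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# decision stumps


@dataclass(frozen=True)
class DecisionStump:
    """One-split tree: ``x[feature] <= threshold`` -> left, else right."""

    feature_index: int
    threshold: float
    left: float
    right: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.where(X[:, self.feature_index] <= self.threshold, self.left, self.right)

    def to_dict(self) -> dict[str, Any]:
        return {
            "feature_index": self.feature_index,
            "threshold": self.threshold,
            "left": self.left,
            "right": self.right,
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "DecisionStump":
        return cls(
            feature_index=int(data["feature_index"]),
            threshold=float(data["threshold"]),
            left=float(data["left"]),
            right=float(data["right"]),
        )


def fit_stump(
    X: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[DecisionStump, float]:
    """Weighted-error-minimizing stump over all (feature, midpoint, polarity).

    Ties are broken by lowest feature index, then lowest threshold, then
    the polarity with the negative class on the left.  Returns the stump
    and its weighted 0/1 error.  If every feature is constant the stump
    degenerates to a weighted majority vote on both sides.
    """
    X = np.asarray(X, dtype=float)
    y = to_signed(y)
    w = np.asarray(w, dtype=float)
    n, d = X.shape
    if n < 2:
        raise BoostingError("need at least 2 samples to fit a stump")
    total_pos = float(w[y == 1].sum())
    total_neg = float(w[y == -1].sum())
    best: tuple[float, int, float, int] | None = None  # (error, feature, thr, polarity)
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        ws = w[order]
        distinct = np.nonzero(xs[:-1] < xs[1:])[0]
        if distinct.size == 0:
            continue
        pos_left = np.cumsum(np.where(ys == 1, ws, 0.0))
        neg_left = np.cumsum(np.where(ys == -1, ws, 0.0))
        for i in distinct:
            thr = 0.5 * (xs[i] + xs[i + 1])
            # polarity -1: left side predicts -1 (errors: pos on left, neg on right)
            err_neg_left = pos_left[i] + (total_neg - neg_left[i])
            err_pos_left = neg_left[i] + (total_pos - pos_left[i])
            for polarity, err in ((-1, err_neg_left), (1, err_pos_left)):
                cand = (float(err), j, float(thr), polarity)
                if best is None or (
                    cand[0] < best[0] - 1e-15
                    or (abs(cand[0] - best[0]) <= 1e-15 and cand[1:] < best[1:])
                ):
                    best = cand
    if best is None:
        majority = 1 if total_pos >= total_neg else -1
        logger.warning("all features constant; returning majority-vote stump")
        stump = DecisionStump(0, math.inf, float(majority), float(majority))
        return stump, float(min(total_pos, total_neg))
    err, j, thr, polarity = best
    stump = DecisionStump(j, thr, float(polarity), float(-polarity))
    return stump, err


# ---------------------------------------------------------------------------
# AdaBoost-M1


class AdaBoostM1:
    """AdaBoost-M1 over decision stumps with exponential reweighting.

    Labels may be given as 0/1 or -1/+1; predictions are returned on the
    same convention the model was trained with.
    """

    def __init__(self, n_rounds: int = 50) -> None:
        if n_rounds < 0:
            raise BoostingError("n_rounds must be non-negative")
        self.n_rounds = n_rounds
        self.stumps: list[DecisionStump] = []
        self.alphas: list[float] = []
        self.errors_: list[float] = []
        self._binary_labels = True
        self._prior_sign = 1
        self._n_features: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AdaBoostM1":
        X = np.asarray(X, dtype=float)
        raw = np.asarray(y)
        self._binary_labels = set(np.unique(raw).tolist()) <= {0, 1}
        y = to_signed(raw)
        if np.unique(y).size < 2:
            raise BoostingError("training labels contain a single class")
        n = len(y)
        self._n_features = X.shape[1]
        self._prior_sign = 1 if (y == 1).sum() >= (y == -1).sum() else -1
        w = np.full(n, 1.0 / n)
        self.stumps, self.alphas, self.errors_ = [], [], []
        self.weight_history_: list[np.ndarray] = [w.copy()]
        for m in range(self.n_rounds):
            stump, eps = fit_stump(X, y, w)
            if eps >= 0.5:
                if m == 0:
                    raise BoostingError(
                        f"no stump beats weighted error 0.5 (got {eps:.4f}); "
                        "the AdaBoost-M1 weak-learning condition is violated"
                    )
                logger.info("round %d: weighted error %.4f >= 0.5; stopping", m, eps)
                break
            eps_eff = max(eps, _ALPHA_CAP_EPS)
            alpha = 0.5 * math.log((1.0 - eps_eff) / eps_eff)
            self.stumps.append(stump)
            self.alphas.append(alpha)
            self.errors_.append(float(eps))
            if eps == 0.0:
                break
            pred = stump.predict(X)
            w = w * np.exp(-alpha * y * pred)
            w = w / w.sum()
            self.weight_history_.append(w.copy())
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Ensemble margin sum(alpha_m h_m(x)); the prior sign if empty."""
        X = np.asarray(X, dtype=float)
        if self._n_features is not None and X.shape[1] != self._n_features:
            raise BoostingError(
                f"expected {self._n_features} features, got {X.shape[1]}"
            )
        margin = np.zeros(len(X))
        for stump, alpha in zip(self.stumps, self.alphas):
            margin += alpha * stump.predict(X)
        if not self.stumps:
            margin += float(self._prior_sign)
        return margin

    def predict(self, X: np.ndarray) -> np.ndarray:
        signed = np.where(self.decision_function(X) >= 0.0, 1, -1)
        return to_binary(signed) if self._binary_labels else signed

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return self.decision_function(X)

    def to_dict(self) -> dict[str, Any]:
        return {
            "model": "adaboost_m1",
            "version": 1,
            "n_rounds": self.n_rounds,
            "binary_labels": self._binary_labels,
            "prior_sign": self._prior_sign,
            "n_features": self._n_features,
            "alphas": list(self.alphas),
            "stumps": [s.to_dict() for s in self.stumps],
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "AdaBoostM1":
        model = cls(n_rounds=int(data["n_rounds"]))
        model._binary_labels = bool(data["binary_labels"])
        model._prior_sign = int(data["prior_sign"])
        model._n_features = data["n_features"]
        model.alphas = [float(a) for a in data["alphas"]]
        model.stumps = [DecisionStump.from_dict(s) for s in data["stumps"]]
        return model


# ---------------------------------------------------------------------------
# regularized gradient boosting


@dataclass
class _TreeNode:
    """Regression tree node; a leaf when ``feature_index`` is None."""

    value: float = 0.0
    feature_index: int | None = None
    threshold: float = 0.0
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X))
        self._fill(X, np.arange(len(X)), out)
        return out

    def _fill(self, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
        if self.feature_index is None:
            out[idx] = self.value
            return
        mask = X[idx, self.feature_index] <= self.threshold
        assert self.left is not None and self.right is not None
        self.left._fill(X, idx[mask], out)
        self.right._fill(X, idx[~mask], out)

    def to_dict(self) -> dict[str, Any]:
        if self.feature_index is None:
            return {"value": self.value}
        assert self.left is not None and self.right is not None
        return {
            "feature_index": self.feature_index,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "_TreeNode":
        if "feature_index" not in data:
            return cls(value=float(data["value"]))
        return cls(
            feature_index=int(data["feature_index"]),
            threshold=float(data["threshold"]),
            left=cls.from_dict(data["left"]),
            right=cls.from_dict(data["right"]),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class RegularizedGradientBoosting:
    """Additive trees on log-loss gradients with L2-penalized leaves.

    Defaults follow the configuration used for the disease-gene task:
    500 trees, learning rate 0.1, depth limit 3, lambda 5.
    """

    def __init__(
        self,
        n_trees: int = 500,
        learning_rate: float = 0.1,
        max_depth: int = 3,
        lambda_l2: float = 5.0,
        min_gain: float = 1e-12,
    ) -> None:
        if n_trees < 0 or learning_rate <= 0 or max_depth < 1 or lambda_l2 < 0:
            raise BoostingError("invalid gradient-boosting configuration")
        self.n_trees = n_trees
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.lambda_l2 = lambda_l2
        self.min_gain = min_gain
        self.trees: list[_TreeNode] = []
        self.base_score = 0.0
        self.train_loss_: list[float] = []
        self._n_features: int | None = None

    # -- tree construction --------------------------------------------

    def _leaf_value(self, g_sum: float, h_sum: float) -> float:
        return -g_sum / (h_sum + self.lambda_l2)

    def _best_split(
        self, X: np.ndarray, g: np.ndarray, h: np.ndarray, idx: np.ndarray
    ) -> tuple[float, int, float] | None:
        """(gain, feature, threshold) of the best second-order split."""
        Xs = X[idx]
        gs, hs = g[idx], h[idx]
        n = len(idx)
        if n < 2:
            return None
        order = np.argsort(Xs, axis=0, kind="stable")
        x_sorted = np.take_along_axis(Xs, order, axis=0)
        g_sorted = np.take_along_axis(gs[:, None].repeat(Xs.shape[1], 1), order, axis=0)
        h_sorted = np.take_along_axis(hs[:, None].repeat(Xs.shape[1], 1), order, axis=0)
        GL = np.cumsum(g_sorted, axis=0)[:-1]
        HL = np.cumsum(h_sorted, axis=0)[:-1]
        G, H = float(gs.sum()), float(hs.sum())
        GR, HR = G - GL, H - HL
        lam = self.lambda_l2
        parent = G * G / (H + lam)
        gains = 0.5 * (GL**2 / (HL + lam) + GR**2 / (HR + lam) - parent)
        valid = x_sorted[:-1] < x_sorted[1:]
        gains = np.where(valid, gains, -np.inf)
        # prefer the lowest feature index, then the lowest split position
        flat = np.argmax(gains.T)
        j, i = divmod(int(flat), gains.shape[0])
        gain = float(gains[i, j])
        if not np.isfinite(gain) or gain <= self.min_gain:
            return None
        thr = 0.5 * float(x_sorted[i, j] + x_sorted[i + 1, j])
        return gain, j, thr

    def _build_tree(
        self, X: np.ndarray, g: np.ndarray, h: np.ndarray, idx: np.ndarray, depth: int
    ) -> _TreeNode:
        g_sum, h_sum = float(g[idx].sum()), float(h[idx].sum())
        if depth >= self.max_depth:
            return _TreeNode(value=self._leaf_value(g_sum, h_sum))
        split = self._best_split(X, g, h, idx)
        if split is None:
            return _TreeNode(value=self._leaf_value(g_sum, h_sum))
        _, j, thr = split
        mask = X[idx, j] <= thr
        return _TreeNode(
            feature_index=j,
            threshold=thr,
            left=self._build_tree(X, g, h, idx[mask], depth + 1),
            right=self._build_tree(X, g, h, idx[~mask], depth + 1),
        )

    # -- training / prediction ----------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegularizedGradientBoosting":
        X = np.asarray(X, dtype=float)
        y = to_binary(y).astype(float)
        self._n_features = X.shape[1]
        prior = float(np.clip(y.mean(), 1e-15, 1.0 - 1e-15))
        self.base_score = math.log(prior / (1.0 - prior))
        self.trees, self.train_loss_ = [], []
        if np.unique(y).size < 2:
            logger.warning("single-class labels; model predicts the prior only")
            self.train_loss_.append(log_loss(y, np.full(len(y), prior)))
            return self
        F = np.full(len(y), self.base_score)
        idx = np.arange(len(y))
        for _ in range(self.n_trees):
            p = _sigmoid(F)
            g = p - y
            h = p * (1.0 - p)
            tree = self._build_tree(X, g, h, idx, depth=0)
            self.trees.append(tree)
            F = F + self.learning_rate * tree.predict(X)
            self.train_loss_.append(log_loss(y, _sigmoid(F)))
        return self

    def raw_score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._n_features is not None and X.shape[1] != self._n_features:
            raise BoostingError(
                f"expected {self._n_features} features, got {X.shape[1]}"
            )
        F = np.full(len(X), self.base_score)
        for tree in self.trees:
            F = F + self.learning_rate * tree.predict(X)
        return F

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.raw_score(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)

    def to_dict(self) -> dict[str, Any]:
        return {
            "model": "regularized_gradient_boosting",
            "version": 1,
            "n_trees": self.n_trees,
            "learning_rate": self.learning_rate,
            "max_depth": self.max_depth,
            "lambda_l2": self.lambda_l2,
            "base_score": self.base_score,
            "n_features": self._n_features,
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RegularizedGradientBoosting":
        model = cls(
            n_trees=int(data["n_trees"]),
            learning_rate=float(data["learning_rate"]),
            max_depth=int(data["max_depth"]),
            lambda_l2=float(data["lambda_l2"]),
        )
        model.base_score = float(data["base_score"])
        model._n_features = data["n_features"]
        model.trees = [_TreeNode.from_dict(t) for t in data["trees"]]
        return model


# ---------------------------------------------------------------------------
# thin functional layer and baselines


def fit_adaboost(X: np.ndarray, y: np.ndarray, n_rounds: int = 50) -> AdaBoostM1:
    return AdaBoostM1(n_rounds=n_rounds).fit(X, y)


def fit_gbm(
    X: np.ndarray, y: np.ndarray, config: dict[str, Any] | None = None
) -> RegularizedGradientBoosting:
    return RegularizedGradientBoosting(**(config or {})).fit(X, y)


def predict(model: Any, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Uniform (labels, scores) prediction over every supported model."""
    labels = model.predict(X)
    if hasattr(model, "predict_score"):
        scores = model.predict_score(X)
    elif hasattr(model, "predict_proba"):
        scores = model.predict_proba(X)[:, 1]
    elif hasattr(model, "decision_function"):
        scores = model.decision_function(X)
    else:
        scores = labels.astype(float)
    return np.asarray(labels), np.asarray(scores)


class SklearnClassifier:
    """Adapter putting scikit-learn estimators behind the same contract."""

    def __init__(self, estimator: Any, name: str) -> None:
        self.estimator = estimator
        self.name = name

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SklearnClassifier":
        self.estimator.fit(np.asarray(X, dtype=float), to_binary(y))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(X)[:, 1]
        return self.estimator.decision_function(X)


BASELINES = ("nb", "svm", "svm_rbf", "knn", "rf")


def make_baseline(name: str, seed: int = 0, **params: Any) -> SklearnClassifier:
    """NB / linear SVM / RBF SVM / KNN / random-forest comparison models."""
    name = name.lower()
    if name == "nb":
        est = GaussianNB(**params)
    elif name == "svm":
        est = SVC(kernel="linear", random_state=seed, **params)
    elif name == "svm_rbf":
        est = SVC(kernel="rbf", random_state=seed, **params)
    elif name == "knn":
        est = KNeighborsClassifier(**params)
    elif name == "rf":
        est = RandomForestClassifier(random_state=seed, **params)
    else:
        raise BoostingError(f"unknown baseline {name!r}; expected one of {BASELINES}")
    return SklearnClassifier(est, name)


def save_model(model: Any, path: str) -> None:
    with open(path, "wt", encoding="utf-8") as handle:
        json.dump(model.to_dict(), handle, indent=2, sort_keys=True)


def load_model(path: str) -> Any:
    with open(path, "rt", encoding="utf-8") as handle:
        data = json.load(handle)
    kind = data.get("model")
    if kind == "adaboost_m1":
        return AdaBoostM1.from_dict(data)
    if kind == "regularized_gradient_boosting":
        return RegularizedGradientBoosting.from_dict(data)
    raise BoostingError(f"unknown serialized model kind {kind!r}")
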