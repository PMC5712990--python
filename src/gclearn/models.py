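"""Supervised causal-graph predictors.

Two scikit-learn-style estimators map scenario features to a causal graph:

* :class:`CellBasedGraphClassifier` (CBC) — one L2-regularised logistic
  regression per off-diagonal cell of the configuration matrix; each model
  predicts whether its cell is 1.
* :class:`MatrixBasedGraphClassifier` (MBC) — a single multinomial logistic
  regression over all 2^(M(M-1)) configurations; per-cell scores are the
  marginal posterior mass of the configurations in which the cell is 1.

Both consume the identical feature matrix, standardise it with training-set
statistics, and expose per-trial M x M cell-score matrices in [0, 1] whose
threshold sweep yields ROC curves comparable with the Geweke baseline.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .simulate import CausalGraph, graph_to_index, index_to_graph, offdiag_pairs

__all__ = [
    "CellBasedGraphClassifier",
    "MatrixBasedGraphClassifier",
    "cost_threshold",
    "train_cbc",
    "train_mbc",
    "predict_cell_scores",
    "predict_graph",
]


def cost_threshold(reward_tp: float = 1.0, penalty_fp: float = 3.0) -> float:
    """Posterior threshold at which predicting an edge breaks even.

    Predict 1 iff p * reward_tp > (1 - p) * penalty_fp, i.e. p > penalty /
    (reward + penalty).  The default +1 / -3 cost model gives 0.75.
    """
    return penalty_fp / (reward_tp + penalty_fp)


class _ConstantCell:
    """Fallback predictor for a cell with a single class in training data."""

    def __init__(self, value: float):
        self.value = float(value)

    def predict_proba(self, X):
        p1 = np.full(X.shape[0], self.value)
        return np.column_stack([1.0 - p1, p1])


def _validate_features(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    return X


class _GraphClassifierBase(BaseEstimator, ClassifierMixin):
    def __init__(
        self,
        n_channels: int = 3,
        C: float = 1.0,
        threshold: float = 0.5,
        max_iter: int = 1000,
        tol: float = 1e-4,
        random_state: int | None = None,
    ):
        self.n_channels = n_channels
        self.C = C
        self.threshold = threshold
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _lr(self) -> LogisticRegression:
        # l2 penalty (the sklearn default), strength 1/C
        return LogisticRegression(
            C=self.C,
            solver="lbfgs",
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        )

    def _start_fit(self, X, y):
        X = _validate_features(X)
        y = np.asarray(y, dtype=int)
        if y.shape[0] != X.shape[0]:
            raise ValueError("feature matrix and labels disagree on n_trials")
        n_free = self.n_channels * (self.n_channels - 1)
        if y.min() < 0 or y.max() >= 2**n_free:
            raise ValueError("graph index labels out of range for n_channels")
        self.n_features_in_ = X.shape[1]
        self.scaler_ = StandardScaler().fit(X)
        return self.scaler_.transform(X), y

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "scaler_")
        X = _validate_features(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.scaler_.transform(X)

    def predict_graph(self, X, threshold: float | None = None) -> np.ndarray:
        """Binary configuration matrices from thresholded cell scores.

        Off-diagonal entry = 1 iff its score exceeds the threshold; the
        diagonal is set to 1 by convention.
        """
        threshold = self.threshold if threshold is None else threshold
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        scores = self.predict_cell_scores(X)
        n = scores.shape[0]
        M = self.n_channels
        graphs = np.zeros((n, M, M), dtype=int)
        graphs[:, np.arange(M), np.arange(M)] = 1
        for (i, j) in offdiag_pairs(M):
            graphs[:, i, j] = (scores[:, i, j] > threshold).astype(int)
        return graphs

    def predict(self, X) -> np.ndarray:
        """Graph-index labels from thresholded cell scores."""
        graphs = self.predict_graph(X)
        return np.array([graph_to_index(CausalGraph(g)) for g in graphs])


class CellBasedGraphClassifier(_GraphClassifierBase):
    """CBC: one binary logistic model per off-diagonal cell (M(M-1) models)."""

    def fit(self, X, y):
        Xs, y = self._start_fit(X, y)
        M = self.n_channels
        pairs = offdiag_pairs(M)
        graphs = np.stack([index_to_graph(k, M).entries for k in y])
        self.pairs_ = pairs
        self.models_ = {}
        self.classes_ = np.unique(y)
        for k, (i, j) in enumerate(pairs):
            target = graphs[:, i, j]
            if len(np.unique(target)) < 2:
                warnings.warn(
                    f"cell ({i},{j}) has a single class in training data; "
                    "using a constant predictor"
                )
                self.models_[(i, j)] = _ConstantCell(target.mean())
                continue
            self.models_[(i, j)] = self._lr().fit(Xs, target)
        return self

    def predict_cell_scores(self, X) -> np.ndarray:
        """(n, M, M) posterior P(cell = 1); diagonal is NaN (undefined)."""
        Xs = self._check_X(X)
        M = self.n_channels
        out = np.full((Xs.shape[0], M, M), np.nan)
        for (i, j), model in self.models_.items():
            out[:, i, j] = model.predict_proba(Xs)[:, 1]
        return out


class MatrixBasedGraphClassifier(_GraphClassifierBase):
    """MBC: one multinomial logistic model over all 2^(M(M-1)) graphs."""

    def fit(self, X, y):
        Xs, y = self._start_fit(X, y)
        if len(np.unique(y)) < 2:
            raise ValueError("matrix-based training needs at least two classes")
        n_classes = 2 ** (self.n_channels * (self.n_channels - 1))
        if len(np.unique(y)) < n_classes:
            warnings.warn(
                f"only {len(np.unique(y))} of {n_classes} configurations "
                "present in training data; absent classes get zero posterior"
            )
        self.model_ = self._lr().fit(Xs, y)
        self.classes_ = self.model_.classes_
        # cell membership of each observed class: (n_classes, n_pairs)
        pairs = offdiag_pairs(self.n_channels)
        self.pairs_ = pairs
        self._membership_ = np.stack(
            [
                [index_to_graph(int(k), self.n_channels).entries[i, j]
                 for (i, j) in pairs]
                for k in self.classes_
            ]
        ).astype(float)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Class posteriors over the observed graph indices (rows sum to 1)."""
        return self.model_.predict_proba(self._check_X(X))

    def predict_cell_scores(self, X) -> np.ndarray:
        """Marginal cell posteriors: sum of class posteriors with cell = 1."""
        posteriors = self.predict_proba(X)
        marg = posteriors @ self._membership_  # (n, n_pairs)
        M = self.n_channels
        out = np.full((posteriors.shape[0], M, M), np.nan)
        for k, (i, j) in enumerate(self.pairs_):
            out[:, i, j] = np.clip(marg[:, k], 0.0, 1.0)
        return out


# ---------------------------------------------------------------------------
# thin functional wrappers


def train_cbc(features, labels, reg_strength: float = 1.0, seed: int | None = None,
              n_channels: int = 3) -> CellBasedGraphClassifier:
    return CellBasedGraphClassifier(
        n_channels=n_channels, C=reg_strength, random_state=seed
    ).fit(features, labels)


def train_mbc(features, labels, reg_strength: float = 1.0, seed: int | None = None,
              n_channels: int = 3) -> MatrixBasedGraphClassifier:
    return MatrixBasedGraphClassifier(
        n_channels=n_channels, C=reg_strength, random_state=seed
    ).fit(features, labels)


def predict_cell_scores(model, features) -> np.ndarray:
    return model.predict_cell_scores(features)


def predict_graph(model, features, threshold: float = 0.5) -> np.ndarray:
    return model.predict_graph(features, threshold=threshold)
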