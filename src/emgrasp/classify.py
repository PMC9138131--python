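"""Seven classifiers on projected features under five-fold cross-validation.

Kinds: LDA (Fisher discriminant classifier), NB (Gaussian naive Bayes),
KNN (k=3, Euclidean), SVML / SVMB / SVMP (linear / RBF / degree-3
polynomial SVM, cost 1, gamma 1, one-vs-one), and NN (a 4-14-5
feed-forward net with tan-sigmoid hidden layer and linear outputs,
trained by full-batch gradient descent with momentum on a one-hot MSE
loss).

Cross-validation fits the min-max normalizer, the projector and the
classifier inside each fold on the training portion only; the t-SNE
projector, having no out-of-sample map, embeds train and test rows
jointly with labels withheld.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from emgrasp.features import FeatureDataset, SymmetricMinMaxScaler
from emgrasp.metrics import classification_error
from emgrasp.projection import (DEFAULT_K, LDAProjector, PCAProjector,
                                SRELMProjector, TSNEEmbedder)

CLASSIFIER_KINDS = ("LDA", "NB", "KNN", "SVML", "SVMB", "SVMP", "NN")


@dataclass
class ClassifierSpec:
    """A classifier kind plus hyperparameter overrides and a training seed."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; "
                             f"choose from {CLASSIFIER_KINDS}")


class MomentumNNClassifier(BaseEstimator, ClassifierMixin):
    """Three-layer feed-forward net: 4 inputs, tan-sigmoid hidden layer
    (14 units), linear outputs, one per class.

    Trained by full-batch gradient descent (learning rate 0.01, momentum
    0.9, 500 epochs) on the mean-squared error against one-hot targets;
    prediction is the argmax of the linear outputs.  Weight initialization
    is seeded (scaled normal) so fits are reproducible.

    Inputs are internally min-max scaled to [-1, 1] (the conventional
    preprocessing of tan-sigmoid networks), so training is insensitive to
    the absolute scale of the projected features.
    """

    def __init__(self, hidden: int = 14, input_dim: int = 4,
                 learning_rate: float = 0.01, momentum: float = 0.9,
                 epochs: int = 500, seed: int = 0):
        self.hidden = hidden
        self.input_dim = input_dim
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MomentumNNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"NN input layer is fixed at {self.input_dim} neurons; "
                f"got {X.shape[1]}-D features")
        self.classes_ = np.unique(y)
        c = len(self.classes_)
        T = (y[:, None] == self.classes_[None, :]).astype(float)
        self.input_min_ = X.min(axis=0)
        self.input_span_ = np.where(np.ptp(X, axis=0) == 0, 1.0,
                                    np.ptp(X, axis=0))
        X = self._scale(X)
        n, m = X.shape
        rng = np.random.default_rng(self.seed)
        W1 = rng.normal(0.0, 1.0 / np.sqrt(m), size=(m, self.hidden))
        b1 = np.zeros(self.hidden)
        W2 = rng.normal(0.0, 1.0 / np.sqrt(self.hidden), size=(self.hidden, c))
        b2 = np.zeros(c)
        vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
        vW2 = np.zeros_like(W2); vb2 = np.zeros_like(b2)
        for _ in range(self.epochs):
            H = np.tanh(X @ W1 + b1)
            O = H @ W2 + b2
            dO = 2.0 * (O - T) / (n * c)
            gW2 = H.T @ dO
            gb2 = dO.sum(axis=0)
            dH = (dO @ W2.T) * (1.0 - H * H)
            gW1 = X.T @ dH
            gb1 = dH.sum(axis=0)
            vW1 = self.momentum * vW1 - self.learning_rate * gW1
            vb1 = self.momentum * vb1 - self.learning_rate * gb1
            vW2 = self.momentum * vW2 - self.learning_rate * gW2
            vb2 = self.momentum * vb2 - self.learning_rate * gb2
            W1 += vW1; b1 += vb1; W2 += vW2; b2 += vb2
        self.W1_, self.b1_, self.W2_, self.b2_ = W1, b1, W2, b2
        return self

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (X - self.input_min_) / self.input_span_ - 1.0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = self._scale(np.asarray(X, dtype=float))
        return np.tanh(X @ self.W1_ + self.b1_) @ self.W2_ + self.b2_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def make_classifier(spec: ClassifierSpec):
    """Instantiate the estimator for a spec.

    Reference hyperparameters: KNN k=3; all SVMs cost 1; RBF/poly gamma 1;
    polynomial degree 3, coef0 0; NN 4-14-c.
    """
    kind, p = spec.kind, spec.params
    if kind == "LDA":
        return LinearDiscriminantAnalysis(**p)
    if kind == "NB":
        return GaussianNB(**p)
    if kind == "KNN":
        return KNeighborsClassifier(n_neighbors=p.get("k", 3))
    if kind == "SVML":
        return SVC(kernel="linear", C=p.get("cost", 1.0))
    if kind == "SVMB":
        return SVC(kernel="rbf", C=p.get("cost", 1.0), gamma=p.get("gamma", 1.0))
    if kind == "SVMP":
        # inhomogeneous kernel (gamma x.x' + 1)^3: the homogeneous form
        # (coef0=0) is degenerate on small-magnitude projected features
        return SVC(kernel="poly", C=p.get("cost", 1.0),
                   gamma=p.get("gamma", 1.0), degree=p.get("degree", 3),
                   coef0=p.get("coef0", 1.0))
    if kind == "NN":
        return MomentumNNClassifier(
            hidden=p.get("hidden", 14), input_dim=p.get("input_dim", 4),
            learning_rate=p.get("learning_rate", 0.01),
            momentum=p.get("momentum", 0.9), epochs=p.get("epochs", 500),
            seed=spec.seed)
    raise ValueError(f"unknown classifier kind {kind!r}")


def make_folds(n_or_data: int | FeatureDataset, n_folds: int = 5,
               seed: int = 0) -> np.ndarray:
    """Seeded random partition into fold ids 1..n_folds (sizes differ by
    at most one row)."""
    n = n_or_data if isinstance(n_or_data, int) else n_or_data.n
    if n < n_folds:
        raise ValueError(f"cannot split {n} rows into {n_folds} folds")
    folds = np.empty(n, dtype=int)
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for fold_id, (_, test_idx) in enumerate(splitter.split(np.arange(n)), start=1):
        folds[test_idx] = fold_id
    return folds


def _fit_projection(projection: str | None, X_train: np.ndarray,
                    X_test: np.ndarray, y_train: np.ndarray, k: int,
                    seed: int, params: dict) -> tuple[np.ndarray, np.ndarray]:
    if projection is None:
        return X_train, X_test
    method = projection.upper()
    if method == "PCA":
        model = PCAProjector(k=k, **params).fit(X_train)
    elif method == "LDA":
        model = LDAProjector(k=k, **params).fit(X_train, y_train)
    elif method == "SRELM":
        model = SRELMProjector(seed=seed, **params).fit(X_train, y_train)
    elif method == "TSNE":
        stacked = np.vstack([X_train, X_test])
        Y = TSNEEmbedder(k=k, seed=seed, **params).fit_transform(stacked)
        return Y[:len(X_train)], Y[len(X_train):]
    else:
        raise ValueError(f"unknown projection method {projection!r}")
    return model.transform(X_train), model.transform(X_test)


def run_fold(spec: ClassifierSpec, data: FeatureDataset, train_mask: np.ndarray,
             test_mask: np.ndarray, projection: str | None = None,
             k: int = DEFAULT_K, seed: int = 0,
             projection_params: dict | None = None) -> float:
    """Normalize, project and classify one train/test split; returns the
    test error in percent."""
    projection_params = projection_params or {}
    y = data.grasp
    scaler = SymmetricMinMaxScaler().fit(data.X[train_mask])
    X_train = scaler.transform(data.X[train_mask])
    X_test = scaler.transform(data.X[test_mask])
    Y_train, Y_test = _fit_projection(projection, X_train, X_test,
                                      y[train_mask], k, seed, projection_params)
    clf = make_classifier(spec)
    clf.fit(Y_train, y[train_mask])
    return classification_error(y[test_mask], clf.predict(Y_test))


def crossvalidate(spec: ClassifierSpec, data: FeatureDataset,
                  folds: np.ndarray, projection: str | None = None,
                  k: int = DEFAULT_K, seed: int = 0,
                  projection_params: dict | None = None,
                  return_folds: bool = False):
    """Mean test error (percent) over the folds of a FoldPlan.

    The normalizer, projector and classifier are refitted inside every
    fold on the training portion only.
    """
    folds = np.asarray(folds)
    if len(folds) != data.n:
        raise ValueError("fold plan length must match the dataset")
    errors = []
    for fold_id in np.unique(folds):
        test_mask = folds == fold_id
        errors.append(run_fold(spec, data, ~test_mask, test_mask, projection,
                               k, seed, projection_params))
    errors = np.array(errors)
    return (float(errors.mean()), errors) if return_folds else float(errors.mean())


def grid_search(kind: str, data: FeatureDataset, grid: Sequence[dict],
                folds: np.ndarray, projection: str | None = None,
                k: int = DEFAULT_K, seed: int = 0) -> tuple[ClassifierSpec, float]:
    """Exhaustive hyperparameter search by cross-validated error.

    Ties resolve to the earliest grid entry.  Returns (best spec, error).
    """
    if not grid:
        raise ValueError("grid must contain at least one point")
    best_spec, best_error = None, np.inf
    for params in grid:
        spec = ClassifierSpec(kind=kind, params=dict(params), seed=seed)
        error = crossvalidate(spec, data, folds, projection, k, seed)
        if error < best_error:
            best_spec, best_error = spec, error
    return best_spec, best_error


def srelm_grid_search(data: FeatureDataset, folds: np.ndarray,
                      alphas: Sequence[float] = tuple(range(1, 11)),
                      node_counts: Sequence[int] = tuple(range(50, 1501, 50)),
                      classifier: ClassifierSpec | None = None,
                      seed: int = 0) -> tuple[int, float, float]:
    """Exhaustive (L, alpha) search for the SRELM projection by
    cross-validated classification error; ties break to smaller L, then
    smaller alpha.  Returns (best L, best alpha, best error)."""
    classifier = classifier or ClassifierSpec("KNN", seed=seed)
    best = None
    for L in sorted(node_counts):
        for alpha in sorted(alphas):
            error = crossvalidate(classifier, data, folds, projection="SRELM",
                                  seed=seed,
                                  projection_params={"L": L, "alpha": alpha})
            key = (error, L, alpha)
            if best is None or key < best:
                best = key
    error, L, alpha = best
    return L, alpha, error
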