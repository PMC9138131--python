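"""Cluster-quality statistics for projected feature sets: SI, MSA, RI.

* SI (separability index): for each class, half the Mahalanobis distance
  to the nearest other class mean under the pairwise-averaged covariance
  S = (S_i + S_j)/2, averaged over classes.  Higher = better separated
  clusters.
* MSA (mean semi-principal axis): per class, the geometric mean of the
  class ellipsoid's semi-axes (square roots of the top-k covariance
  eigenvalues), averaged over classes.  Lower = more compact clusters.
* RI (repeatability index): per class, half the Mahalanobis distance
  between the training and testing class means under the training
  covariance, averaged over classes.  Lower = more consistent train/test
  feature distributions.

Near-singular covariances get a tiny ridge (1e-9 * trace/dim on the
diagonal) before inversion so degenerate inputs stay computable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

_RIDGE = 1e-9


def _class_partition(X: np.ndarray, y: np.ndarray) -> dict:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    return {cls: X[y == cls] for cls in np.unique(y)}


def _regularized(S: np.ndarray) -> np.ndarray:
    dim = S.shape[0]
    return S + _RIDGE * (np.trace(S) / dim + 1.0e-300) * np.eye(dim)


def _half_mahalanobis(delta: np.ndarray, S: np.ndarray) -> float:
    solved = linalg.solve(_regularized(S), delta, assume_a="pos")
    return 0.5 * float(np.sqrt(max(delta @ solved, 0.0)))


def separability_index(X: np.ndarray, y: np.ndarray) -> float:
    """SI: mean over classes of the minimum half-Mahalanobis distance to
    any other class mean, under S = (S_i + S_j)/2."""
    groups = _class_partition(X, y)
    if len(groups) < 2:
        raise ValueError("separability_index needs at least 2 classes")
    dim = X.shape[1]
    for cls, Xc in groups.items():
        if len(Xc) <= dim:
            raise ValueError(
                f"class {cls!r} has {len(Xc)} rows; need more than dim={dim}")
    means = {cls: Xc.mean(axis=0) for cls, Xc in groups.items()}
    covs = {cls: np.cov(Xc, rowvar=False) for cls, Xc in groups.items()}
    total = 0.0
    for cls_i in groups:
        best = np.inf
        for cls_j in groups:
            if cls_j == cls_i:
                continue
            S = (covs[cls_i] + covs[cls_j]) / 2.0
            best = min(best, _half_mahalanobis(means[cls_i] - means[cls_j], S))
        total += best
    return total / len(groups)


def mean_semi_principal_axis(X: np.ndarray, y: np.ndarray,
                             k: int | None = None) -> float:
    """MSA: mean over classes of the geometric mean of the k largest
    semi-principal axes sqrt(lambda) of the class covariance."""
    groups = _class_partition(X, y)
    dim = X.shape[1]
    k = dim if k is None else k
    if k < 1 or k > dim:
        raise ValueError(f"k must be in 1..{dim}")
    total = 0.0
    for cls, Xc in groups.items():
        if len(Xc) < 2:
            raise ValueError(f"class {cls!r} needs at least 2 rows")
        evals = linalg.eigvalsh(np.cov(Xc, rowvar=False))[::-1][:k]
        if np.any(evals < -1e-8 * max(1.0, abs(evals[0]))):
            raise ValueError("covariance has a significantly negative eigenvalue")
        axes = np.sqrt(np.maximum(evals, 0.0))
        total += float(np.prod(axes) ** (1.0 / k))
    return total / len(groups)


def repeatability_index(X_train: np.ndarray, y_train: np.ndarray,
                        X_test: np.ndarray, y_test: np.ndarray) -> float:
    """RI: mean over classes of half the Mahalanobis distance between the
    training and testing class means under the training covariance."""
    train_groups = _class_partition(X_train, y_train)
    test_groups = _class_partition(X_test, y_test)
    missing = set(train_groups) ^ set(test_groups)
    if missing:
        raise ValueError(f"classes {sorted(missing)} not present in both sets")
    total = 0.0
    for cls, Xc in train_groups.items():
        S = np.cov(Xc, rowvar=False)
        delta = Xc.mean(axis=0) - test_groups[cls].mean(axis=0)
        total += _half_mahalanobis(delta, S)
    return total / len(train_groups)


def classification_error(true_labels, predicted_labels) -> float:
    """Percent misclassified: 100 * (# mismatches) / n."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    if true_labels.size == 0:
        raise ValueError("empty label vectors")
    return 100.0 * float(np.mean(true_labels != predicted_labels))


def cluster_report(X: np.ndarray, y: np.ndarray,
                   X_test: np.ndarray | None = None,
                   y_test: np.ndarray | None = None,
                   k: int | None = None) -> dict:
    """SI and MSA of (X, y); RI too when a test split is supplied."""
    report = {
        "SI": separability_index(X, y),
        "MSA": mean_semi_principal_axis(X, y, k=k),
    }
    if X_test is not None:
        report["RI"] = repeatability_index(X, y, X_test, y_test)
    return report


def scatter_export(X: np.ndarray, y: np.ndarray, positions: np.ndarray,
                   path: str | Path) -> pd.DataFrame:
    """Plotting-ready CSV of the first two components, grasp-colored and
    position-marked."""
    X = np.asarray(X, dtype=float)
    frame = pd.DataFrame({
        "component1": X[:, 0],
        "component2": X[:, 1] if X.shape[1] > 1 else 0.0,
        "grasp": np.asarray(y),
        "position": np.asarray(positions),
    })
    frame.to_csv(path, index=False)
    return frame
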