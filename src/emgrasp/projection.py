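"""Feature projection from 66-D to k = 4: PCA, LDA, SRELM and exact t-SNE.

All four reduce a normalized feature matrix to k = 4 dimensions (the
number of grasp classes minus one).  PCA and LDA are linear; SRELM
(spectral-regression extreme learning machine) is a supervised nonlinear
projection that regresses an orthogonalized class-indicator response onto
a random sigmoid hidden layer; t-SNE is an unsupervised, transductive
embedding with no out-of-sample mapping — train and test rows are
embedded jointly with labels withheld.

PCA/LDA/SRELM follow the sklearn fit/transform contract and can be placed
in sklearn pipelines; t-SNE only offers ``fit_transform``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

PROJECTION_METHODS = ("PCA", "LDA", "SRELM", "TSNE")
DEFAULT_K = 4


class PCAProjector(BaseEstimator, TransformerMixin):
    """Principal-component projection to ``k`` dimensions.

    Thin wrapper around sklearn's exact-SVD PCA exposing the projection
    matrix ``components_`` as an m x k array (columns are the top-k
    eigenvectors of the sample covariance) together with the centering
    mean and the descending eigenvalues.
    """

    def __init__(self, k: int = DEFAULT_K):
        self.k = k

    def fit(self, X: np.ndarray, y=None) -> "PCAProjector":
        X = np.asarray(X, dtype=float)
        if self.k > X.shape[1]:
            raise ValueError(f"k={self.k} exceeds feature dimension {X.shape[1]}")
        if X.shape[0] <= self.k:
            raise ValueError("need more samples than components")
        self._pca = PCA(n_components=self.k, svd_solver="full").fit(X)
        self.components_ = self._pca.components_.T        # m x k
        self.mean_ = self._pca.mean_
        self.eigenvalues_ = self._pca.explained_variance_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "components_")
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_


class LDAProjector(BaseEstimator, TransformerMixin):
    """Fisher discriminant projection: top-k eigenvectors of S_w^{-1} S_b.

    S_w is the pooled within-class scatter, S_b the between-class scatter
    weighted by class counts.  k is capped at c - 1 (S_b has rank c - 1).
    S_w gets a tiny ridge (1e-9 * trace/m on the diagonal) so degenerate
    inputs remain invertible.
    """

    def __init__(self, k: int = DEFAULT_K, ridge: float = 1e-9):
        self.k = k
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LDAProjector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        c = len(self.classes_)
        if c < 2:
            raise ValueError("LDA projection needs at least 2 classes")
        if self.k > c - 1:
            raise ValueError(f"k={self.k} exceeds c-1={c - 1}")
        n, m = X.shape
        mu = X.mean(axis=0)
        S_w = np.zeros((m, m))
        S_b = np.zeros((m, m))
        self.class_means_ = np.empty((c, m))
        self.class_counts_ = np.empty(c, dtype=int)
        for j, cls in enumerate(self.classes_):
            Xj = X[y == cls]
            mu_j = Xj.mean(axis=0)
            self.class_means_[j] = mu_j
            self.class_counts_[j] = len(Xj)
            centered = Xj - mu_j
            S_w += centered.T @ centered
            S_b += len(Xj) * np.outer(mu_j - mu, mu_j - mu)
        S_w_reg = S_w + self.ridge * (np.trace(S_w) / m) * np.eye(m)
        evals, evecs = linalg.eigh(S_b, S_w_reg)
        order = np.argsort(evals)[::-1][:self.k]
        self.eigenvalues_ = evals[order]
        self.scalings_ = evecs[:, order]                   # m x k
        self.S_w_ = S_w
        self.S_b_ = S_b
        self.global_mean_ = mu
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "scalings_")
        return np.asarray(X, dtype=float) @ self.scalings_


def _srelm_sigmoid(d: np.ndarray) -> np.ndarray:
    """Hidden-node activation g(d) = 1 / (1 + e^d).

    This is the mirror image of the conventional logistic; since the
    hidden parameters are drawn sign-symmetrically the function class is
    identical.
    """
    return 1.0 / (1.0 + np.exp(np.clip(d, -500, 500)))


def spectral_responses(y: np.ndarray) -> np.ndarray:
    """Orthonormal class-indicator responses Z (n x (c-1)).

    The c one-hot indicator columns span a c-dimensional space containing
    the all-ones vector; Z is an orthonormal basis of that span with the
    constant direction removed, obtained from a QR factorization of
    [1 | indicators].
    """
    y = np.asarray(y)
    classes = np.unique(y)
    c = len(classes)
    n = len(y)
    indicators = (y[:, None] == classes[None, :]).astype(float)
    M = np.column_stack([np.ones(n), indicators])
    Q, _ = np.linalg.qr(M)
    # column 0 is the constant direction; the last indicator column is
    # linearly dependent, so columns 1..c-1 form the response basis
    return Q[:, 1:c]


class SRELMProjector(BaseEstimator, TransformerMixin):
    """Spectral-regression extreme learning machine projection.

    fit: (1) draw hidden-node parameters (a_i, b_i) ~ U(-1, 1) from the
    seed; (2) hidden layer H with the sigmoid g(d) = 1/(1+e^d);
    (3) orthonormal class-indicator responses Z (c-1 columns);
    (4) ridge solution U = (H^T H + alpha I)^{-1} H^T Z.

    transform reuses the training-stage (a_i, b_i): Y = H_new U, giving
    c - 1 = 4 output dimensions for 5 classes.
    """

    def __init__(self, L: int = 1000, alpha: float = 1.0, seed: int = 0):
        self.L = L
        self.alpha = alpha
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SRELMProjector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        c = len(self.classes_)
        if self.L < c:
            raise ValueError(f"L={self.L} must be at least c={c}")
        n, m = X.shape
        rng = np.random.default_rng(self.seed)
        self.hidden_weights_ = rng.uniform(-1.0, 1.0, size=(m, self.L))
        self.hidden_biases_ = rng.uniform(-1.0, 1.0, size=self.L)
        H = self._hidden(X)
        Z = spectral_responses(y)
        self.Z_ = Z
        A = H.T @ H + self.alpha * np.eye(self.L)
        self.output_weights_ = linalg.solve(A, H.T @ Z, assume_a="pos")
        return self

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return _srelm_sigmoid(X @ self.hidden_weights_ + self.hidden_biases_)

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "output_weights_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.hidden_weights_.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match fitted "
                f"dimension {self.hidden_weights_.shape[0]}")
        return self._hidden(X) @ self.output_weights_


class TSNEEmbedder(BaseEstimator):
    """Exact t-SNE to ``k`` dimensions (no Barnes-Hut approximation).

    Per-point Gaussian bandwidths sigma_i are calibrated by bisection so
    each conditional distribution p_{.|i} has the target perplexity
    (tolerance 1e-5 on log-perplexity, at most 50 iterations).  The joint
    P symmetrizes the conditionals, p_ij = (p_{i|j}+p_{j|i})/(2n).  The
    embedding minimizes KL(P || Q) with Student-t similarities Q by
    gradient descent: learning rate 200, momentum 0.5 switching to 0.8
    after iteration 250, early exaggeration x4 for the first 100 of 1000
    iterations, seeded N(0, 1e-4) initialization.

    Transductive: there is no transform; embed train+test jointly.
    """

    def __init__(self, k: int = DEFAULT_K, perplexity: float = 30.0,
                 n_iter: int = 1000, learning_rate: float = 200.0,
                 early_exaggeration: float = 4.0, seed: int = 0):
        self.k = k
        self.perplexity = perplexity
        self.n_iter = n_iter
        self.learning_rate = learning_rate
        self.early_exaggeration = early_exaggeration
        self.seed = seed

    def _conditional_probabilities(self, D2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row-wise bisection on beta = 1/(2 sigma^2) to hit the target
        perplexity; returns (conditional P, sigma per point)."""
        n = D2.shape[0]
        target = np.log(self.perplexity)
        P = np.zeros((n, n))
        betas = np.ones(n)
        for i in range(n):
            d = np.delete(D2[i], i)
            beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
            for _ in range(50):
                w = np.exp(-d * beta)
                sum_w = w.sum()
                if sum_w <= 0:
                    entropy = 0.0
                    p = w
                else:
                    p = w / sum_w
                    entropy = beta * np.dot(d, p) + np.log(sum_w)
                diff = entropy - target
                if abs(diff) < 1e-5:
                    break
                if diff > 0:
                    beta_lo = beta
                    beta = beta * 2 if beta_hi == np.inf else (beta + beta_hi) / 2
                else:
                    beta_hi = beta
                    beta = beta / 2 if beta_lo == 0 else (beta + beta_lo) / 2
            betas[i] = beta
            P[i, np.arange(n) != i] = p
        return P, np.sqrt(1.0 / (2.0 * betas))

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n <= 3 * self.perplexity:
            raise ValueError(
                f"perplexity {self.perplexity} infeasible for n={n} "
                "(need n > 3*perplexity)")
        sq = np.sum(X * X, axis=1)
        D2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0)
        P_cond, self.sigmas_ = self._conditional_probabilities(D2)
        P = (P_cond + P_cond.T) / (2.0 * n)
        P = np.maximum(P, 1e-12)
        self.P_ = P

        rng = np.random.default_rng(self.seed)
        Y = rng.normal(0.0, 1e-4, size=(n, self.k))
        update = np.zeros_like(Y)
        self.initial_cost_ = None
        for it in range(self.n_iter):
            P_eff = P * self.early_exaggeration if it < 100 else P
            sq_y = np.sum(Y * Y, axis=1)
            num = 1.0 / (1.0 + np.maximum(
                sq_y[:, None] + sq_y[None, :] - 2.0 * Y @ Y.T, 0.0))
            np.fill_diagonal(num, 0.0)
            Q = np.maximum(num / num.sum(), 1e-12)
            if self.initial_cost_ is None:
                self.initial_cost_ = float(np.sum(P * np.log(P / Q)))
            W = (P_eff - Q) * num
            grad = 4.0 * (W.sum(axis=1)[:, None] * Y - W @ Y)
            momentum = 0.5 if it < 250 else 0.8
            update = momentum * update - self.learning_rate * grad
            Y = Y + update
            Y = Y - Y.mean(axis=0)
        sq_y = np.sum(Y * Y, axis=1)
        num = 1.0 / (1.0 + np.maximum(
            sq_y[:, None] + sq_y[None, :] - 2.0 * Y @ Y.T, 0.0))
        np.fill_diagonal(num, 0.0)
        Q = np.maximum(num / num.sum(), 1e-12)
        self.cost_ = float(np.sum(P * np.log(P / Q)))
        self.embedding_ = Y
        return Y


_SAVED_ATTRS = {
    "PCAProjector": ("components_", "mean_", "eigenvalues_"),
    "LDAProjector": ("scalings_", "eigenvalues_", "S_w_", "S_b_",
                     "class_means_", "class_counts_", "global_mean_",
                     "classes_"),
    "SRELMProjector": ("hidden_weights_", "hidden_biases_",
                       "output_weights_", "classes_"),
}


def save_projector(model, path: str | Path) -> None:
    """Serialize a fitted PCA/LDA/SRELM projector (parameters + fitted
    matrices) to a single .npz archive."""
    name = type(model).__name__
    if name not in _SAVED_ATTRS:
        raise ValueError(f"cannot serialize {name}; t-SNE embeddings have "
                         "no reusable parametric form")
    payload = {attr: getattr(model, attr) for attr in _SAVED_ATTRS[name]}
    payload["__class__"] = np.array(name)
    for key, value in model.get_params().items():
        payload[f"__param__{key}"] = np.array(value)
    np.savez(path, **payload)


def load_projector(path: str | Path):
    """Reload a projector saved by :func:`save_projector`, bit-compatibly."""
    with np.load(path, allow_pickle=False) as archive:
        name = str(archive["__class__"])
        cls = {"PCAProjector": PCAProjector, "LDAProjector": LDAProjector,
               "SRELMProjector": SRELMProjector}[name]
        params = {key.removeprefix("__param__"): archive[key].item()
                  for key in archive.files if key.startswith("__param__")}
        model = cls(**params)
        for attr in _SAVED_ATTRS[name]:
            setattr(model, attr, archive[attr])
    return model


def project(method: str, X_train: np.ndarray, X_test: np.ndarray,
            y_train: np.ndarray | None = None, k: int = DEFAULT_K,
            seed: int = 0, **params) -> tuple[np.ndarray, np.ndarray]:
    """Fit-on-train / transform-both for PCA, LDA, SRELM; joint
    transductive embedding (labels withheld) split back by row index for
    t-SNE.  Returns (train_Y, test_Y), both n x k."""
    method = method.upper()
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if method == "PCA":
        model = PCAProjector(k=k, **params).fit(X_train)
    elif method == "LDA":
        if y_train is None:
            raise ValueError("LDA projection requires training labels")
        model = LDAProjector(k=k, **params).fit(X_train, y_train)
    elif method == "SRELM":
        if y_train is None:
            raise ValueError("SRELM projection requires training labels")
        model = SRELMProjector(seed=seed, **params).fit(X_train, y_train)
    elif method == "TSNE":
        stacked = np.vstack([X_train, X_test])
        Y = TSNEEmbedder(k=k, seed=seed, **params).fit_transform(stacked)
        return Y[:len(X_train)], Y[len(X_train):]
    else:
        raise ValueError(f"unknown projection method {method!r}; "
                         f"choose from {PROJECTION_METHODS}")
    return model.transform(X_train), model.transform(X_test)
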