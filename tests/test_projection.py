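"""PCA, LDA, SRELM and t-SNE projections against independent oracles."""

from itertools import permutations

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.cluster import KMeans

from emgrasp.metrics import separability_index
from emgrasp.projection import (LDAProjector, PCAProjector, SRELMProjector,
                                TSNEEmbedder, load_projector, project,
                                save_projector, spectral_responses)
from tests.conftest import gaussian_classes


# ---------------------------------------------------------------- PCA

def stretched_cloud(rng, n=500):
    X = rng.standard_normal((n, 2))
    X[:, 0] *= 10.0
    theta = 0.3
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    return X @ R.T


def test_pca_first_axis_matches_eigen_oracle():
    rng = np.random.default_rng(0)
    X = stretched_cloud(rng)
    model = PCAProjector(k=1).fit(X)
    evals, evecs = np.linalg.eigh(np.cov(X, rowvar=False))
    oracle_axis = evecs[:, np.argmax(evals)]
    cosine = abs(model.components_[:, 0] @ oracle_axis)
    assert np.degrees(np.arccos(np.clip(cosine, -1, 1))) < 2.0


def test_pca_full_rank_reconstruction():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((100, 6))
    model = PCAProjector(k=6).fit(X)
    Y = model.transform(X)
    np.testing.assert_allclose(Y @ model.components_.T + model.mean_, X,
                               atol=1e-8)


def test_pca_eigenvalues_sorted_and_isotropic_case():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((20_000, 4))
    model = PCAProjector(k=4).fit(X)
    assert np.all(np.diff(model.eigenvalues_) <= 1e-12)
    # isotropic Gaussian: all eigenvalues equal within sampling error
    assert model.eigenvalues_[0] / model.eigenvalues_[-1] < 1.1


def test_pca_projection_is_linear():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((200, 5))
    model = PCAProjector(k=2).fit(X)
    centered = X - model.mean_
    np.testing.assert_allclose(
        model.transform(model.mean_ + 2.0 * centered),
        2.0 * model.transform(X), atol=1e-10)


def test_pca_rejects_k_above_dimension():
    with pytest.raises(ValueError):
        PCAProjector(k=7).fit(np.zeros((10, 5)))


# ---------------------------------------------------------------- LDA

def fisher_ratio(X, y, direction):
    z = X @ direction
    classes = np.unique(y)
    grand = z.mean()
    between = sum((z[y == c].mean() - grand) ** 2 * np.sum(y == c)
                  for c in classes)
    within = sum(np.sum((z[y == c] - z[y == c].mean()) ** 2) for c in classes)
    return between / within


def test_lda_axis_maximizes_fisher_ratio():
    """The fitted 1-D axis beats 1000 random directions (brute-force
    oracle) on two separated spherical classes in 10-D."""
    rng = np.random.default_rng(4)
    X, y = gaussian_classes(rng, [np.zeros(10), np.r_[1.0, np.zeros(9)]],
                            n_per_class=300)
    model = LDAProjector(k=1).fit(X, y)
    fitted = fisher_ratio(X, y, model.scalings_[:, 0])
    directions = rng.standard_normal((1000, 10))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    best_random = max(fisher_ratio(X, y, d) for d in directions)
    assert fitted >= 0.99 * best_random


def test_lda_shuffled_labels_collapse_eigenvalues():
    rng = np.random.default_rng(5)
    X, y = gaussian_classes(rng, [np.zeros(6), np.r_[3.0, np.zeros(5)]],
                            n_per_class=200)
    informative = LDAProjector(k=1).fit(X, y).eigenvalues_[0]
    shuffled = LDAProjector(k=1).fit(X, rng.permutation(y)).eigenvalues_[0]
    assert shuffled < informative / 20


def test_lda_k_capped_at_classes_minus_one():
    rng = np.random.default_rng(6)
    X, y = gaussian_classes(rng, 2.0 * np.eye(5), n_per_class=30)
    assert LDAProjector(k=4).fit(X, y).scalings_.shape == (5, 4)
    with pytest.raises(ValueError):
        LDAProjector(k=5).fit(X, y)
    with pytest.raises(ValueError):
        LDAProjector(k=1).fit(X, np.zeros(len(y)))


def test_lda_separable_two_class_threshold_error_zero():
    """On linearly separable 2-class data a brute-force threshold on the
    1-D LDA projection achieves training error 0."""
    rng = np.random.default_rng(7)
    X, y = gaussian_classes(rng, [np.zeros(4), np.r_[8.0, np.zeros(3)]],
                            n_per_class=100)
    z = LDAProjector(k=1).fit(X, y).transform(X).ravel()
    candidates = (np.sort(z)[1:] + np.sort(z)[:-1]) / 2
    errors = [min(np.mean((z > t) != y), np.mean((z < t) != y))
              for t in candidates]
    assert min(errors) == 0.0


def test_lda_scatter_matrices_are_symmetric():
    rng = np.random.default_rng(8)
    X, y = gaussian_classes(rng, np.eye(3), n_per_class=50)
    model = LDAProjector(k=2).fit(X, y)
    np.testing.assert_allclose(model.S_w_, model.S_w_.T)
    np.testing.assert_allclose(model.S_b_, model.S_b_.T)


# ---------------------------------------------------------------- SRELM

def test_spectral_responses_orthonormal_and_width():
    y = np.repeat(np.arange(5), 6)
    Z = spectral_responses(y)
    assert Z.shape == (30, 4)
    np.testing.assert_allclose(Z.T @ Z, np.eye(4), atol=1e-10)
    # orthogonal to the constant direction too
    np.testing.assert_allclose(Z.sum(axis=0), 0.0, atol=1e-10)


def test_srelm_output_weights_match_ridge_optimizer_oracle():
    """U agrees to 1e-5 with a generic numerical minimizer of the ridge
    objective sum_i (u^T h(x_i) - z_i)^2 + alpha sum_j u_j^2."""
    rng = np.random.default_rng(9)
    X = rng.standard_normal((30, 5))
    y = np.repeat(np.arange(3), 10)
    model = SRELMProjector(L=10, alpha=1.0, seed=0).fit(X, y)
    H = model._hidden(X)
    Z = model.Z_
    for col in range(Z.shape[1]):
        def objective(u, col=col):
            r = H @ u - Z[:, col]
            return r @ r + model.alpha * u @ u
        res = minimize(objective, np.zeros(10), method="L-BFGS-B",
                       tol=1e-14)
        np.testing.assert_allclose(model.output_weights_[:, col], res.x,
                                   atol=1e-5)


def test_srelm_projects_to_classes_minus_one():
    rng = np.random.default_rng(10)
    X, y = gaussian_classes(rng, np.eye(5), n_per_class=20)
    model = SRELMProjector(L=50, seed=1).fit(X, y)
    assert model.output_weights_.shape == (50, 4)
    assert model.transform(X).shape == (100, 4)
    with pytest.raises(ValueError):
        SRELMProjector(L=3).fit(X, y)  # L < c


def test_srelm_transform_reuses_training_nodes_and_is_deterministic():
    rng = np.random.default_rng(11)
    X, y = gaussian_classes(rng, 2 * np.eye(5), n_per_class=20)
    model = SRELMProjector(L=40, seed=3).fit(X, y)
    manual = model._hidden(X) @ model.output_weights_
    np.testing.assert_array_equal(model.transform(X), manual)
    np.testing.assert_array_equal(model.transform(X), model.transform(X))
    refit = SRELMProjector(L=40, seed=3).fit(X, y)
    np.testing.assert_array_equal(refit.hidden_weights_, model.hidden_weights_)


def test_srelm_rejects_feature_dimension_mismatch():
    rng = np.random.default_rng(12)
    X, y = gaussian_classes(rng, np.eye(5), n_per_class=20)
    model = SRELMProjector(L=20, seed=0).fit(X, y)
    with pytest.raises(ValueError):
        model.transform(np.zeros((3, 7)))


def test_srelm_ridge_shrinkage_is_monotone():
    rng = np.random.default_rng(13)
    X, y = gaussian_classes(rng, np.eye(5), n_per_class=20)
    norms = [np.linalg.norm(
        SRELMProjector(L=30, alpha=alpha, seed=2).fit(X, y).output_weights_)
        for alpha in [0.1, 1.0, 10.0, 100.0]]
    assert np.all(np.diff(norms) < 0)


def test_srelm_separates_better_than_pca_on_clustered_data():
    rng = np.random.default_rng(14)
    X, y = gaussian_classes(rng, 1.5 * np.eye(5), cov_scale=0.6,
                            n_per_class=60, dim=5)
    pca_Y = PCAProjector(k=4).fit(X).transform(X)
    srelm_Y = SRELMProjector(L=200, seed=4).fit(X, y).transform(X)
    assert separability_index(srelm_Y, y) > separability_index(pca_Y, y)


# ---------------------------------------------------------------- t-SNE

@pytest.fixture(scope="module")
def tsne_result():
    rng = np.random.default_rng(15)
    means = np.zeros((3, 66))
    means[1, :10] = 6.0
    means[2, 10:20] = 6.0
    X, y = gaussian_classes(rng, means, n_per_class=100)
    model = TSNEEmbedder(k=2, perplexity=30, seed=0)
    Y = model.fit_transform(X)
    return model, X, y, Y


def test_tsne_probability_normalizations(tsne_result):
    model, X, _, _ = tsne_result
    n = X.shape[0]
    assert model.P_.shape == (n, n)
    np.testing.assert_allclose(model.P_, model.P_.T, atol=1e-12)
    assert abs(model.P_.sum() - 1.0) < 1e-6
    # conditional rows each sum to 1: rebuild them from the bandwidths
    sq = np.sum(X * X, axis=1)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    P_cond, _ = model._conditional_probabilities(D2)
    np.testing.assert_allclose(P_cond.sum(axis=1), 1.0, atol=1e-6)


def test_tsne_cost_decreases(tsne_result):
    model = tsne_result[0]
    assert model.cost_ >= 0.0
    assert model.cost_ < model.initial_cost_


def test_tsne_recovers_three_clusters(tsne_result):
    _, _, y, Y = tsne_result
    pred = KMeans(n_clusters=3, n_init=10, random_state=0).fit_predict(Y)
    agreement = max(np.mean(np.array(mapping)[pred] == y)
                    for mapping in permutations(range(3)))
    assert agreement >= 0.95


def test_tsne_rejects_infeasible_perplexity():
    with pytest.raises(ValueError):
        TSNEEmbedder(perplexity=30).fit_transform(np.zeros((50, 3)))


# ---------------------------------------------------------------- project()

def test_project_outputs_four_columns_for_all_methods():
    rng = np.random.default_rng(16)
    X, y = gaussian_classes(rng, 2 * np.eye(5), n_per_class=40)
    X_test = X[:20]
    for method in ("PCA", "LDA", "SRELM", "TSNE"):
        params = {"perplexity": 20.0, "n_iter": 100} if method == "TSNE" else {}
        if method == "SRELM":
            params = {"L": 30}
        Ytr, Yts = project(method, X, X_test, y, k=4, seed=0, **params)
        assert Ytr.shape == (200, 4) and Yts.shape == (20, 4)


def test_project_pca_equals_fit_transform_composition():
    rng = np.random.default_rng(17)
    X = rng.standard_normal((60, 8))
    Ytr, Yts = project("PCA", X, X[:5], k=3)
    model = PCAProjector(k=3).fit(X)
    np.testing.assert_array_equal(Ytr, model.transform(X))
    np.testing.assert_array_equal(Yts, model.transform(X[:5]))


def test_project_tsne_row_bookkeeping():
    """The joint embedding's train rows equal the rows the splitter hands
    back, independent of how the test block is re-split afterwards."""
    rng = np.random.default_rng(18)
    X = rng.standard_normal((120, 6))
    Ytr, Yts = project("TSNE", X[:80], X[80:], k=2, seed=1,
                       perplexity=15.0, n_iter=100)
    joint = TSNEEmbedder(k=2, seed=1, perplexity=15.0,
                         n_iter=100).fit_transform(X)
    np.testing.assert_array_equal(np.vstack([Ytr, Yts]), joint)
    np.testing.assert_array_equal(Ytr, joint[:80])


def test_fitted_projectors_serialize_bit_compatibly(tmp_path):
    rng = np.random.default_rng(19)
    X, y = gaussian_classes(rng, 2 * np.eye(5), n_per_class=30)
    models = [PCAProjector(k=4).fit(X),
              LDAProjector(k=4).fit(X, y),
              SRELMProjector(L=40, alpha=2.0, seed=5).fit(X, y)]
    for model in models:
        path = tmp_path / f"{type(model).__name__}.npz"
        save_projector(model, path)
        restored = load_projector(path)
        assert restored.get_params() == model.get_params()
        np.testing.assert_array_equal(restored.transform(X),
                                      model.transform(X))
    embedder = TSNEEmbedder()
    with pytest.raises(ValueError):
        save_projector(embedder, tmp_path / "tsne.npz")


def test_project_unknown_method_rejected():
    with pytest.raises(ValueError):
        project("UMAP", np.zeros((10, 3)), np.zeros((2, 3)))
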