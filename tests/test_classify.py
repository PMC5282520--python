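import numpy as np
import pytest

from lensbench.classify import (
    ELMClassifier,
    KNNConfig,
    elm_train,
    knn_predict,
    svm_train,
)

from .oracles import knn_bruteforce


@pytest.fixture()
def blobs(rng):
    """Two well-separated 2-D Gaussian blobs, 20 points per class."""
    X = np.vstack([rng.normal(-2, 0.5, size=(20, 2)), rng.normal(2, 0.5, size=(20, 2))])
    y = np.array([0] * 20 + [1] * 20)
    return X, y


class TestSVM:
    def test_separable_1d(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        model = svm_train(X, y)
        assert np.array_equal(model.predict(X), y)
        # decision boundary between the classes
        assert model.decision_scores([[-1.0]])[0] < 0 < model.decision_scores([[1.0]])[0]

    def test_duplicated_dataset_same_decision_function(self, blobs):
        X, y = blobs
        a = svm_train(X, y)
        b = svm_train(np.vstack([X, X]), np.concatenate([y, y]))
        grid = np.mgrid[-3:3:7j, -3:3:7j].reshape(2, -1).T
        np.testing.assert_allclose(a.decision_scores(grid), b.decision_scores(grid), atol=1e-6)

    def test_xor_not_linearly_separable(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]] * 5)
        y = np.array([0, 0, 1, 1] * 5)
        model = svm_train(X, y, kernel="linear")
        assert (model.predict(X) == y).mean() <= 0.75

    def test_label_flip_flips_scores(self, blobs):
        X, y = blobs
        s = svm_train(X, y).decision_scores(X)
        s_flipped = svm_train(X, 1 - y).decision_scores(X)
        assert np.all(np.sign(s) == -np.sign(s_flipped))

    def test_zero_feature_invariance(self, blobs):
        """Appending an identically-zero feature leaves predictions unchanged."""
        X, y = blobs
        a = svm_train(X, y).predict(X)
        Xz = np.hstack([X, np.zeros((len(X), 1))])
        b = svm_train(Xz, y).predict(Xz)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            svm_train(np.zeros((4, 2)), np.zeros(4, dtype=int))

    def test_training_order_invariance(self, blobs, rng):
        X, y = blobs
        perm = rng.permutation(len(y))
        a = svm_train(X, y).predict(X)
        b = svm_train(X[perm], y[perm]).predict(X)
        np.testing.assert_array_equal(a, b)


class TestELM:
    def test_square_system_solved_exactly(self, rng):
        """With as many hidden units as distinct samples, H beta = T exactly."""
        X = rng.normal(size=(10, 3))
        y = np.array([0, 1] * 5)
        model = elm_train(X, y, n_hidden=10, seed=0)
        H = model._hidden(model.scaler.transform(X))
        T = np.eye(2)[y]
        np.testing.assert_allclose(H @ model.beta, T, atol=1e-8)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_seed_determinism(self, blobs):
        X, y = blobs
        a = elm_train(X, y, seed=5)
        b = elm_train(X, y, seed=5)
        np.testing.assert_array_equal(a.beta, b.beta)
        c = elm_train(X, y, seed=6)
        assert not np.allclose(a.beta, c.beta)

    def test_beta_matches_pinv_oracle(self, rng):
        X = rng.normal(size=(10, 4))
        y = np.array([0, 1] * 5)
        model = elm_train(X, y, n_hidden=5, seed=1)
        H = model._hidden(model.scaler.transform(X))
        T = np.eye(2)[y]
        # SVD pseudo-inverse oracle
        u, s, vt = np.linalg.svd(H, full_matrices=False)
        beta_oracle = vt.T @ np.diag(1 / s) @ u.T @ T
        np.testing.assert_allclose(model.beta, beta_oracle, atol=1e-8)

    def test_residual_is_minimal(self, rng):
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(int)
        model = elm_train(X, y, n_hidden=8, seed=2)
        H = model._hidden(model.scaler.transform(X))
        T = np.eye(2)[y]
        base = np.linalg.norm(H @ model.beta - T)
        for _ in range(100):
            delta = rng.normal(0, 1e-3, size=model.beta.shape)
            assert np.linalg.norm(H @ (model.beta + delta) - T) >= base - 1e-12

    def test_constant_feature_no_nan(self):
        X = np.ones((8, 3))
        X[:4, 0] = 0.0
        y = np.array([0] * 4 + [1] * 4)
        model = elm_train(X, y, n_hidden=4, seed=0)
        assert np.all(np.isfinite(model.decision_scores(X)))


class TestKNN:
    def test_query_equals_training_point(self, blobs):
        X, y = blobs
        labels, _ = knn_predict(X, y, X[[0, 25]], KNNConfig(k=1))
        np.testing.assert_array_equal(labels, [y[0], y[25]])

    def test_k_equals_n_gives_majority(self, rng):
        X = rng.normal(size=(15, 2))
        y = np.array([1] * 9 + [0] * 6)
        labels, scores = knn_predict(X, y, rng.normal(size=(5, 2)), KNNConfig(k=15))
        np.testing.assert_array_equal(labels, 1)
        np.testing.assert_allclose(scores, 9 / 15)

    def test_matches_bruteforce_oracle(self, rng):
        X = rng.normal(size=(20, 2))
        y = rng.integers(0, 2, size=20)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        queries = rng.normal(size=(8, 2))
        labels, scores = knn_predict(X, y, queries, KNNConfig(k=5))
        mu, sd = X.mean(axis=0), X.std(axis=0)
        for q, lab, sc in zip(queries, labels, scores):
            lab_o, sc_o = knn_bruteforce((X - mu) / sd, y, (q - mu) / sd, 5)
            assert lab == lab_o
            assert sc == pytest.approx(sc_o)

    def test_global_scaling_invariance(self, blobs):
        X, y = blobs
        q = np.array([[0.3, -0.4], [1.5, 1.0]])
        a, _ = knn_predict(X, y, q, KNNConfig(k=5))
        b, _ = knn_predict(X * 10, y, q * 10, KNNConfig(k=5))
        np.testing.assert_array_equal(a, b)

    def test_even_split_goes_negative(self):
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        labels, scores = knn_predict(X, y, np.array([[1.0]]), KNNConfig(k=4))
        assert scores[0] == 0.5 and labels[0] == 0

    def test_k_too_large_rejected(self, blobs):
        X, y = blobs
        with pytest.raises(ValueError, match="exceeds training size"):
            knn_predict(X, y, X[:1], KNNConfig(k=100))

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "canberra"])
    def test_all_metrics_run(self, blobs, metric):
        X, y = blobs
        labels, scores = knn_predict(X, y, X[:4], KNNConfig(k=3, distance=metric))
        assert labels.shape == (4,)
        assert np.all((scores >= 0) & (scores <= 1))
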