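"""Vector-space classifiers: soft-margin SVM, extreme learning machine, kNN.

All three standardize features (zero mean, unit variance per feature, fit on
the training data only) before fitting: the benchmark's feature blocks mix
raw moments, probabilities and histogram counts whose scales differ by
orders of magnitude. All three expose hard labels and a continuous score
(used for ROC curves): the SVM decision value, the ELM output-unit margin,
and the kNN positive-neighbor fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SVMClassifier",
    "svm_train",
    "svm_predict",
    "svm_score",
    "ELMClassifier",
    "elm_train",
    "elm_predict",
    "KNNConfig",
    "knn_predict",
]


def _validate_training(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    return X, y


# --------------------------------------------------------------------------
# SVM (libsvm via scikit-learn; linear or degree-3 polynomial kernel)
# --------------------------------------------------------------------------


@dataclass
class SVMClassifier:
    kernel: str = "linear"
    C: float = 1.0
    scaler: StandardScaler = field(default_factory=StandardScaler, repr=False)
    svc: SVC | None = field(default=None, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMClassifier":
        X, y = _validate_training(X, y)
        if self.kernel not in ("linear", "polynomial"):
            raise ValueError(f"kernel must be linear or polynomial, got {self.kernel!r}")
        kernel = "poly" if self.kernel == "polynomial" else "linear"
        Xs = self.scaler.fit_transform(X)
        # gamma=1/dim, coef0=0, degree=3: the classic libsvm defaults
        self.svc = SVC(kernel=kernel, C=self.C, degree=3, gamma="auto", coef0=0.0)
        self.svc.fit(Xs, y)
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        if self.svc is None:
            raise RuntimeError("classifier is not fitted")
        return self.svc.decision_function(self.scaler.transform(np.asarray(X, dtype=np.float64)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.svc is None:
            raise RuntimeError("classifier is not fitted")
        return self.svc.predict(self.scaler.transform(np.asarray(X, dtype=np.float64)))


def svm_train(X: np.ndarray, y: np.ndarray, kernel: str = "linear", C: float = 1.0) -> SVMClassifier:
    return SVMClassifier(kernel=kernel, C=C).fit(X, y)


def svm_score(model: SVMClassifier, X: np.ndarray) -> np.ndarray:
    return model.decision_scores(X)


def svm_predict(model: SVMClassifier, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


# --------------------------------------------------------------------------
# Extreme learning machine
# --------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class ELMClassifier:
    """Single-hidden-layer feedforward net with a frozen random hidden layer.

    Input weights and biases are drawn uniformly from [-1, 1]; the output
    weights beta are the minimum-norm least-squares solution of H beta = T,
    i.e. beta = pinv(H) T, with T the one-hot class indicator matrix.
    """

    n_hidden: int = 80
    seed: int = 0
    scaler: StandardScaler = field(default_factory=StandardScaler, repr=False)
    input_weights: np.ndarray | None = field(default=None, repr=False)
    biases: np.ndarray | None = field(default=None, repr=False)
    beta: np.ndarray | None = field(default=None, repr=False)

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(X @ self.input_weights + self.biases)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ELMClassifier":
        X, y = _validate_training(X, y)
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        rng = np.random.default_rng(self.seed)
        Xs = self.scaler.fit_transform(X)
        self.input_weights = rng.uniform(-1.0, 1.0, size=(X.shape[1], self.n_hidden))
        self.biases = rng.uniform(-1.0, 1.0, size=self.n_hidden)
        H = self._hidden(Xs)
        T = np.eye(2)[y]  # one-hot: column 0 = negative, column 1 = positive
        self.beta, *_ = np.linalg.lstsq(H, T, rcond=None)
        return self

    def output(self, X: np.ndarray) -> np.ndarray:
        if self.beta is None:
            raise RuntimeError("classifier is not fitted")
        Xs = self.scaler.transform(np.asarray(X, dtype=np.float64))
        return self._hidden(Xs) @ self.beta

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        out = self.output(X)
        return out[:, 1] - out[:, 0]  # margin of positive unit over negative

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) >= 0).astype(int)


def elm_train(X: np.ndarray, y: np.ndarray, n_hidden: int = 80, seed: int = 0) -> ELMClassifier:
    return ELMClassifier(n_hidden=n_hidden, seed=seed).fit(X, y)


def elm_predict(model: ELMClassifier, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = model.decision_scores(X)
    return (scores >= 0).astype(int), scores


# --------------------------------------------------------------------------
# k-nearest neighbors
# --------------------------------------------------------------------------

_KNN_METRICS = ("euclidean", "manhattan", "canberra")


@dataclass(frozen=True)
class KNNConfig:
    k: int = 10
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.distance not in _KNN_METRICS:
            raise ValueError(f"distance must be one of {_KNN_METRICS}, got {self.distance!r}")


def knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    cfg: KNNConfig = KNNConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote among the k nearest training points.

    Deterministic tie-breaking: equidistant neighbors are ordered by training
    index; an evenly split vote goes to the negative class. The returned
    score is the positive-neighbor fraction.
    """
    train_X, train_y = _validate_training(train_X, train_y)
    test_X = np.asarray(test_X, dtype=np.float64)
    if cfg.k > len(train_X):
        raise ValueError(f"k={cfg.k} exceeds training size {len(train_X)}")
    scaler = StandardScaler().fit(train_X)
    metric = "cityblock" if cfg.distance == "manhattan" else cfg.distance
    dists = cdist(scaler.transform(test_X), scaler.transform(train_X), metric=metric)
    # stable sort on distance => equal distances resolved by training index
    order = np.argsort(dists, axis=1, kind="stable")[:, : cfg.k]
    pos_fraction = train_y[order].mean(axis=1)
    labels = (pos_fraction > 0.5).astype(int)  # exact split -> negative
    return labels, pos_fraction
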