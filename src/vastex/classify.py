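"""Soft-margin SVM and k-nearest-neighbor classification of feature vectors.

Both classifiers operate on z-scored features (statistics estimated on the
training set only) because the raw feature scales span several orders of
magnitude.  The SVM defaults to an RBF kernel with the median-pairwise-
distance bandwidth heuristic; the KNN uses Euclidean distance with k = 5 and
scores test points by the fraction of abnormal neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.svm import SVC

from .cohort import ABNORMAL


@dataclass
class Standardizer:
    """Per-feature z-scoring with training statistics; drops constant features."""

    mean: np.ndarray
    sd: np.ndarray
    keep: np.ndarray  # boolean mask of non-constant features

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.any():
            raise ValueError("all features have zero variance on the training set")
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s)")
        return cls(mean=mean, sd=sd, keep=keep)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X[:, self.keep] - self.mean[self.keep]) / self.sd[self.keep]

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.sd[self.keep] + self.mean[self.keep]


def median_distance_gamma(X: np.ndarray) -> float:
    """RBF bandwidth heuristic: gamma = 1 / (2 m²), m = median pairwise distance."""
    d = pdist(np.asarray(X, dtype=float))
    m = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return float(1.0 / (2.0 * m * m))


@dataclass
class TrainedClassifier:
    """A fitted SVM or KNN plus the standardization used at training time."""

    kind: str                      # "svm" | "knn"
    model: object
    scaler: Standardizer
    classes: tuple[str, str]       # (negative, positive) = (normal, abnormal)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return predict(self, X)


def _check_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    return y


def train_svm(
    X, y, penalty: float = 1.0, kernel: str = "rbf", gamma: float | None = None
) -> TrainedClassifier:
    """Fit a soft-margin SVM; ``penalty`` is the slack-vs-margin tradeoff C > 0.

    ``kernel`` is ``"rbf"`` (default, bandwidth from the median-distance
    heuristic unless ``gamma`` is given) or ``"linear"``.
    """
    if penalty <= 0:
        raise ValueError("penalty must be > 0")
    y = _check_labels(y)
    scaler = Standardizer.fit(np.asarray(X, dtype=float))
    Z = scaler.transform(X)
    if kernel == "rbf" and gamma is None:
        gamma = median_distance_gamma(Z)
    svc = SVC(C=penalty, kernel=kernel, gamma=gamma if kernel == "rbf" else "scale",
              tol=1e-6)
    svc.fit(Z, y)
    neg = [c for c in svc.classes_ if c != ABNORMAL][0] if ABNORMAL in svc.classes_ \
        else svc.classes_[0]
    pos = ABNORMAL if ABNORMAL in svc.classes_ else svc.classes_[1]
    return TrainedClassifier("svm", svc, scaler, (neg, pos))


class _KNN:
    """Majority-vote Euclidean KNN with a stable distance sort, so ties at
    the k-th distance are resolved by training-set index order."""

    def __init__(self, Z: np.ndarray, y: np.ndarray, k: int):
        self.Z = Z
        self.y = y
        self.k = k
        self.classes_ = np.unique(y)

    def predict_for(self, X: np.ndarray, positive, negative):
        order = np.argsort(cdist(X, self.Z), axis=1, kind="stable")
        frac = (self.y[order[:, :self.k]] == positive).mean(axis=1)
        labels = np.where(frac > 0.5, positive, negative)
        if self.k % 2 == 0:  # even-k vote ties: defer to the nearest neighbor
            tie = frac == 0.5
            labels[tie] = self.y[order[tie, 0]]
        return labels, frac


def train_knn(X, y, k: int = 5) -> TrainedClassifier:
    """Store the training set for majority-vote Euclidean KNN prediction.

    Distance ties are resolved by training-set index order; with two classes
    and odd k, vote ties cannot occur.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    y = _check_labels(y)
    if k > len(y):
        raise ValueError(f"k={k} exceeds training size {len(y)}")
    scaler = Standardizer.fit(np.asarray(X, dtype=float))
    Z = scaler.transform(X)
    knn = _KNN(Z, np.asarray(y), k)
    neg = [c for c in knn.classes_ if c != ABNORMAL][0] if ABNORMAL in knn.classes_ \
        else knn.classes_[0]
    pos = ABNORMAL if ABNORMAL in knn.classes_ else knn.classes_[1]
    return TrainedClassifier("knn", knn, scaler, (neg, pos))


def predict(model: TrainedClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and continuous scores (higher = more abnormal).

    SVM scores are signed decision-function values oriented so the positive
    class is abnormal; KNN scores are the abnormal vote fraction among the k
    neighbors.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.scaler.mean.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training "
            f"dimension {model.scaler.mean.shape[0]}"
        )
    Z = model.scaler.transform(X)
    if model.kind == "svm":
        labels = model.model.predict(Z)
        scores = model.model.decision_function(Z)
        # sklearn orients the decision function toward classes_[1]
        if model.model.classes_[1] != model.classes[1]:
            scores = -scores
    else:
        labels, scores = model.model.predict_for(Z, model.classes[1],
                                                 model.classes[0])
    return labels, np.asarray(scores, dtype=float)
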