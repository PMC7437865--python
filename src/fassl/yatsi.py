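"""Two-stage semi-supervised classification (YATSI) and the base classifiers.

Stage 1 trains a pluggable supervised base classifier on the N labeled rows
and uses it to *pre-label* the M unlabeled rows.  Stage 2 is a weighted
nearest-neighbor vote over the combined store: labeled rows carry weight
1.0, pre-labeled rows carry weight ``F * (N / M)`` — with F = 1 the
unlabeled block as a whole counts as much as the labeled block, however
large M is.  The wrapper works with any estimator exposing fit/predict;
SVM (RBF), random forest and kNN factories are provided.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


class _ConstantClassifier:
    """Degenerate predictor used when the labeled set holds a single class."""

    def __init__(self, label):
        self.label = label

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.label, dtype=object)


def make_base_classifier(name: str, seed: int | None = None):
    """Factory for the supervised base classifiers (tokens svm|rf|knn)."""
    if name == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=3)
    raise ValueError(f"unknown base classifier {name!r}; choose from svm|rf|knn")


def _fit_base(base, X, y):
    """Fit, degrading gracefully to a constant predictor on one-class data."""
    if len(np.unique(y)) < 2:
        return _ConstantClassifier(y[0]).fit(X, y)
    est = clone(base) if isinstance(base, BaseEstimator) else base
    est.fit(X, y)
    return est


class YatsiClassifier(ClassifierMixin, BaseEstimator):
    """Yet Another Two-Stage Idea: pre-label, then weighted-kNN classify.

    Parameters
    ----------
    base_estimator : estimator, default kNN(3)
        Supervised stage-1 classifier (must implement fit/predict).
    F : float, default 1.0
        Unlabeled weighting factor; each pre-labeled row gets weight
        ``F * N / M``.  ``F = 0`` disables label propagation entirely and
        the model reduces to weighted kNN over the labeled rows.
    K : int, default 10
        Stage-2 neighbor count (clamped to the store size).
    class_order : sequence, optional
        Tie-break order for the stage-2 vote; defaults to sorted labels.

    Attributes
    ----------
    classes_ : ndarray of class tokens
    store_X_, store_y_, store_w_ : the combined weighted instance store
        (zero-weight rows are omitted: they can never carry a vote).
    """

    def __init__(self, base_estimator=None, F: float = 1.0, K: int = 10, class_order=None):
        self.base_estimator = base_estimator
        self.F = F
        self.K = K
        self.class_order = class_order

    def fit(self, X, y, unlabeled_X=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if len(y) == 0:
            raise ValueError("need at least one labeled sample")
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        base = self.base_estimator if self.base_estimator is not None else KNeighborsClassifier(n_neighbors=3)
        n_fit_neighbors = getattr(base, "n_neighbors", None)
        if n_fit_neighbors is not None and n_fit_neighbors > len(y):
            base = KNeighborsClassifier(n_neighbors=len(y))
        self.base_estimator_ = _fit_base(base, X, y)

        N = X.shape[0]
        blocks_X, blocks_y, blocks_w = [X], [y], [np.ones(N)]
        if unlabeled_X is not None:
            U = np.asarray(unlabeled_X, dtype=float)
            M = U.shape[0]
            w = 0.0 if M == 0 else self.F * N / M
            if M > 0 and w > 0.0:
                blocks_X.append(U)
                blocks_y.append(np.asarray(self.base_estimator_.predict(U), dtype=object))
                blocks_w.append(np.full(M, w))
        self.store_X_ = np.vstack(blocks_X)
        self.store_y_ = np.concatenate(blocks_y)
        self.store_w_ = np.concatenate(blocks_w)
        if self.class_order is not None:
            self.classes_ = np.asarray([c for c in self.class_order if c in set(y)], dtype=object)
        else:
            self.classes_ = np.asarray(sorted(set(y), key=str), dtype=object)
        return self

    def predict(self, X):
        if not hasattr(self, "store_X_"):
            raise RuntimeError("YatsiClassifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = min(self.K, self.store_X_.shape[0])
        if k < self.K:
            logger.debug("K clamped from %d to store size %d", self.K, k)
        D = cdist(X, self.store_X_)
        class_pos = {c: p for p, c in enumerate(self.classes_)}
        out = np.empty(X.shape[0], dtype=object)
        row_idx = np.arange(self.store_X_.shape[0])
        for q in range(X.shape[0]):
            order = np.lexsort((row_idx, D[q]))[:k]
            scores = np.zeros(len(self.classes_))
            for j in order:
                lab = self.store_y_[j]
                if lab in class_pos:  # pre-labels are base predictions, always known classes
                    scores[class_pos[lab]] += self.store_w_[j]
            out[q] = self.classes_[int(np.argmax(scores))]  # argmax -> first class on ties
        return out


class SupervisedWrapper(ClassifierMixin, BaseEstimator):
    """Pass-through wrapper: trains the base on labeled rows only.

    Gives the active *supervised* comparison track the same fit signature
    as :class:`YatsiClassifier` (the unlabeled block is ignored).
    """

    def __init__(self, base_estimator=None):
        self.base_estimator = base_estimator

    def fit(self, X, y, unlabeled_X=None):
        base = self.base_estimator if self.base_estimator is not None else KNeighborsClassifier(n_neighbors=3)
        n_fit_neighbors = getattr(base, "n_neighbors", None)
        y = np.asarray(y, dtype=object)
        if n_fit_neighbors is not None and n_fit_neighbors > len(y):
            base = KNeighborsClassifier(n_neighbors=len(y))
        self.base_estimator_ = _fit_base(base, np.asarray(X, dtype=float), y)
        self.classes_ = np.asarray(sorted(set(y), key=str), dtype=object)
        return self

    def predict(self, X):
        return np.asarray(self.base_estimator_.predict(np.asarray(X, dtype=float)), dtype=object)


def make_classifier(token: str, seed: int | None = None, F: float = 1.0, K: int = 10,
                    class_order=None):
    """Build a loop-ready classifier from a config token.

    Tokens: ``svm|rf|knn`` (supervised) or ``yatsi-svm|yatsi-rf|yatsi-knn``
    (semi-supervised wrapper around the same bases).
    """
    if token.startswith("yatsi-"):
        base = make_base_classifier(token[len("yatsi-"):], seed)
        return YatsiClassifier(base_estimator=base, F=F, K=K, class_order=class_order)
    return SupervisedWrapper(base_estimator=make_base_classifier(token, seed))
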