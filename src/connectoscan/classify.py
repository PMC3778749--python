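"""Two-class predictors used on connectivity-edge features.

Three canonical classifiers, each with a ``fit(X, y)`` / ``predict(X)``
surface and fully deterministic, documented tie rules:

* :class:`MaxMarginClassifier` — soft-margin linear support-vector
  machine: minimise ½‖ω‖² + C·Σε_k subject to y_k(ωᵀx_k + b) ≥ 1 − ε_k;
  predict sign(ωᵀx + b), with 0 mapped to the positive class.  Features
  are standardised by training mean/sd (sd floor 1e−12).  The quadratic
  programme is solved by scikit-learn's SVC (libsvm) with a tight
  tolerance.
* :class:`PearsonKnnClassifier` — k-nearest-neighbour (default k = 6)
  where similarity is the Pearson correlation between feature vectors;
  majority vote, ties broken by larger summed similarity, then by the
  class of the single most similar neighbour.
* :class:`GaussianNaiveBayes` — argmax_c p(c)·Π_i p(x_i|c) with Gaussian
  per-class, per-feature conditionals, computed in log space; zero
  variances floored at 1e−9 of the pooled variance.  Exact posterior
  ties go to the larger prior, then the lower class index.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "MaxMarginClassifier",
    "PearsonKnnClassifier",
    "GaussianNaiveBayes",
    "CLASSIFIERS",
]


def _check_two_class(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, found {len(classes)}")
    return classes


class MaxMarginClassifier:
    """Linear soft-margin maximum-margin classifier."""

    def __init__(self, C: float = 1.0):
        if C <= 0:
            raise ValueError("C must be positive")
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = _check_two_class(y)
        self._mean = X.mean(axis=0)
        self._sd = np.maximum(X.std(axis=0), 1e-12)
        Xs = (X - self._mean) / self._sd
        ypm = np.where(y == self.classes_[1], 1, -1)
        self._svc = SVC(kernel="linear", C=self.C, tol=1e-8)
        self._svc.fit(Xs, ypm)
        self.coef_ = self._svc.coef_.ravel()
        self.intercept_ = float(self._svc.intercept_[0])
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self._mean.shape[0]:
            raise ValueError("feature dimension mismatch")
        Xs = (X - self._mean) / self._sd
        return Xs @ self.coef_ + self.intercept_

    def predict(self, X):
        d = self.decision_function(X)
        # sign with 0 -> positive class
        return np.where(d >= 0, self.classes_[1], self.classes_[0])


class PearsonKnnClassifier:
    """k-NN with Pearson-correlation similarity (default k = 6)."""

    def __init__(self, k: int = 6):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        # unanimous training labels are fine: the vote is trivial
        self.classes_ = np.unique(y)
        if len(self.classes_) > 2:
            raise ValueError("expected at most 2 classes")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds n_train={X.shape[0]}")
        self._X = X
        self._y = y
        return self

    @staticmethod
    def _correlations(train: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Pearson r of x against every training row; constant vectors
        correlate 0 by convention (with a warning)."""
        xc = x - x.mean()
        xn = np.linalg.norm(xc)
        tc = train - train.mean(axis=1, keepdims=True)
        tn = np.linalg.norm(tc, axis=1)
        if xn < 1e-30 or np.any(tn < 1e-30):
            warnings.warn("constant feature vector: correlation set to 0")
        r = np.zeros(train.shape[0])
        ok = tn >= 1e-30
        if xn >= 1e-30:
            r[ok] = (tc[ok] @ xc) / (tn[ok] * xn)
        return r

    def predict_one(self, x):
        if len(self.classes_) == 1:
            return self.classes_[0]
        r = self._correlations(self._X, np.asarray(x, dtype=float))
        # stable sort: equal similarities keep training order
        order = np.argsort(-r, kind="stable")[: self.k]
        votes_y = self._y[order]
        sims = r[order]
        n1 = int(np.sum(votes_y == self.classes_[1]))
        n0 = len(votes_y) - n1
        if n1 != n0:
            return self.classes_[1] if n1 > n0 else self.classes_[0]
        s1 = sims[votes_y == self.classes_[1]].sum()
        s0 = sims[votes_y == self.classes_[0]].sum()
        if not np.isclose(s1, s0, rtol=0, atol=1e-12):
            return self.classes_[1] if s1 > s0 else self.classes_[0]
        return votes_y[0]  # class of the single most similar neighbour

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return np.asarray([self.predict_one(x) for x in X])


class GaussianNaiveBayes:
    """Naive Bayes with Gaussian conditionals, log-space scoring."""

    def __init__(self, variance_floor_frac: float = 1e-9):
        self.variance_floor_frac = variance_floor_frac

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = _check_two_class(y)
        n = X.shape[0]
        pooled = X.var(axis=0)
        floor = np.maximum(self.variance_floor_frac * pooled, 1e-30)
        self.priors_ = np.array([np.mean(y == c) for c in self.classes_])
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        var = np.stack([X[y == c].var(axis=0) for c in self.classes_])
        if np.any(var < floor):
            warnings.warn("zero-variance feature: variance floored")
        self.vars_ = np.maximum(var, floor)
        return self

    def log_posterior(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        out = np.empty((X.shape[0], 2))
        for ci in range(2):
            ll = -0.5 * (
                np.log(2 * np.pi * self.vars_[ci])
                + (X - self.means_[ci]) ** 2 / self.vars_[ci]
            ).sum(axis=1)
            out[:, ci] = np.log(self.priors_[ci]) + ll
        return out

    def predict(self, X):
        lp = self.log_posterior(X)
        diff = lp[:, 1] - lp[:, 0]
        tol = 1e-12 * np.maximum(1.0, np.abs(lp).max(axis=1))
        pred = np.where(diff > tol, self.classes_[1], self.classes_[0])
        ties = np.abs(diff) <= tol
        if np.any(ties):
            # tie: larger prior wins, then the lower class index
            if self.priors_[1] > self.priors_[0]:
                pred[ties] = self.classes_[1]
            else:
                pred[ties] = self.classes_[0]
        return pred


CLASSIFIERS = {
    "max_margin": MaxMarginClassifier,
    "knn": PearsonKnnClassifier,
    "nb": GaussianNaiveBayes,
}
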