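"""The two model families: Fisher linear discriminant analysis and random forest.

Fisher LDA is implemented directly from the pooled-covariance discriminant.
With class means mu0, mu1, pooled within-class covariance S (maximum-likelihood
divisor n, which makes the boundary invariant to duplicating every training
sample) and class priors pi0, pi1, the discriminant is

    s(x) = w' x + b,   w = (S + ridge*I)^{-1} (mu1 - mu0),
    b = -w' (mu0 + mu1) / 2 + log(pi1 / pi0),

predicting the second class (``classes_[1]``) when s >= 0.  Under the equal
covariance Gaussian model s is the log-odds, so the class-1 posterior is
``expit(s)``.  The ridge coefficient is *relative*: the effective value added
to the diagonal is ``ridge * mean(diag(S))`` (binary presence features in
small folds routinely give a singular S).

The random forest is Breiman's scheme — trees grown to purity on bootstrap
samples with ``mtry`` random candidate features per split, Gini criterion —
realized by :class:`sklearn.ensemble.RandomForestClassifier` behind a wrapper
that fixes the vote-fraction score and the tie rule (ties go to the class
with the larger training prior).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import joblib
import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier

__all__ = ["FisherLDA", "RandomForest", "fit_lda", "fit_forest", "predict"]


class FisherLDA:
    """Two-class Fisher LDA with pooled covariance and optional ridge.

    Parameters
    ----------
    priors : {"empirical", "uniform"}
        Class prior probabilities; empirical priors make an uninformative
        model predict the majority class.
    ridge : float
        Relative regularization: ``ridge * mean(diag(pooled_cov))`` is added
        to the covariance diagonal before inversion.
    """

    def __init__(self, priors: str = "empirical", ridge: float = 1e-6):
        if priors not in ("empirical", "uniform"):
            raise ValueError(f"priors must be 'empirical' or 'uniform', got {priors!r}")
        if ridge < 0:
            raise ValueError("ridge must be non-negative")
        self.priors = priors
        self.ridge = ridge

    def fit(self, X, y) -> "FisherLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        self.classes_, yi = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError(f"exactly two classes required, got {len(self.classes_)}")
        counts = np.bincount(yi, minlength=2)
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples")
        keep = X.std(axis=0) > 0
        self.dropped_ = list(np.nonzero(~keep)[0])
        if not keep.any():
            raise ValueError("all features are constant")
        self._keep = keep
        Xk = X[:, keep]
        mu = np.stack([Xk[yi == k].mean(axis=0) for k in (0, 1)])
        centered = Xk - mu[yi]
        n = len(Xk)
        S = centered.T @ centered / n
        diag_mean = float(np.trace(S)) / S.shape[0]
        self.ridge_ = self.ridge * diag_mean if diag_mean > 0 else self.ridge
        A = S + self.ridge_ * np.eye(S.shape[0])
        delta = mu[1] - mu[0]
        try:
            w = np.linalg.solve(A, delta)
        except np.linalg.LinAlgError:
            w = np.linalg.lstsq(A, delta, rcond=None)[0]
        pri = counts / n if self.priors == "empirical" else np.array([0.5, 0.5])
        self.class_means_ = mu
        self.pooled_covariance_ = S
        self.weights_ = w
        self.intercept_ = float(-0.5 * w @ (mu[0] + mu[1]) + math.log(pri[1] / pri[0]))
        self.priors_ = pri
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._keep.size:
            raise ValueError(
                f"expected {self._keep.size} features, got {X.shape[1]}"
            )
        return X[:, self._keep] @ self.weights_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        # ties at s = 0 go to classes_[1]
        return self.classes_[(self.decision_function(X) >= 0).astype(int)]

    def predict_proba(self, X) -> np.ndarray:
        p1 = expit(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def to_dict(self) -> dict:
        return {
            "kind": "fisher_lda",
            "priors": self.priors,
            "ridge": self.ridge,
            "ridge_effective": self.ridge_,
            "classes": self.classes_.tolist(),
            "keep": self._keep.tolist(),
            "class_means": self.class_means_.tolist(),
            "pooled_covariance": self.pooled_covariance_.tolist(),
            "weights": self.weights_.tolist(),
            "intercept": self.intercept_,
            "class_priors": self.priors_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FisherLDA":
        obj = cls(priors=d["priors"], ridge=d["ridge"])
        obj.classes_ = np.asarray(d["classes"])
        obj._keep = np.asarray(d["keep"], dtype=bool)
        obj.dropped_ = list(np.nonzero(~obj._keep)[0])
        obj.class_means_ = np.asarray(d["class_means"], dtype=float)
        obj.pooled_covariance_ = np.asarray(d["pooled_covariance"], dtype=float)
        obj.weights_ = np.asarray(d["weights"], dtype=float)
        obj.intercept_ = float(d["intercept"])
        obj.priors_ = np.asarray(d["class_priors"], dtype=float)
        obj.ridge_ = float(d["ridge_effective"])
        return obj


class RandomForest:
    """Breiman random forest: bootstrap + random feature subsets, grown to purity.

    ``mtry=None`` uses floor(sqrt(p)); ``mtry=p`` (or `'all'`) makes it a
    bagged-tree ensemble (all features available at each split).  The score is
    the fraction of tree votes for ``classes_[1]``; a 50/50 vote goes to the
    class with the larger training prior (prior ties to ``classes_[1]``).
    Deterministic given ``seed``.
    """

    def __init__(self, n_trees: int = 500, mtry=None, seed: int = 0, oob: bool = False):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if mtry is not None and mtry != "all" and mtry < 1:
            raise ValueError(f"mtry must be >= 1, got {mtry}")
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed
        self.oob = oob

    def fit(self, X, y) -> "RandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(X) < 2:
            raise ValueError("need at least 2 samples")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required")
        p = X.shape[1]
        if self.mtry is None:
            m = max(1, int(math.isqrt(p)))
        elif self.mtry == "all":
            m = p
        else:
            m = min(int(self.mtry), p)
        self.mtry_ = m
        self._rf = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=m,
            criterion="gini",
            bootstrap=True,
            oob_score=self.oob,
            random_state=int(self.seed) % (2**31),
            n_jobs=1,
        )
        self._rf.fit(X, y)
        counts = np.array([(y == c).sum() for c in self.classes_])
        self.priors_ = counts / counts.sum()
        self.oob_estimate_ = float(self._rf.oob_score_) if self.oob else None
        return self

    @property
    def trees(self):
        return self._rf.estimators_

    @property
    def feature_importances_(self) -> np.ndarray:
        return self._rf.feature_importances_

    def predict_proba(self, X) -> np.ndarray:
        # trees are grown to purity, so sklearn's averaged leaf probabilities
        # are exactly the vote fractions
        proba = self._rf.predict_proba(np.asarray(X, dtype=float))
        if proba.shape[1] == 1:  # degenerate single-class guard (unreached post-fit check)
            proba = np.column_stack([proba, 1 - proba])
        return proba

    def predict(self, X) -> np.ndarray:
        p1 = self.predict_proba(X)[:, 1]
        out = np.where(p1 > 0.5, self.classes_[1], self.classes_[0])
        tie = p1 == 0.5
        if tie.any():
            winner = self.classes_[1] if self.priors_[1] >= self.priors_[0] else self.classes_[0]
            out[tie] = winner
        return out

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "RandomForest":
        return joblib.load(path)


def fit_lda(X, y, priors: str = "empirical", ridge: float = 1e-6) -> FisherLDA:
    return FisherLDA(priors=priors, ridge=ridge).fit(X, y)


def fit_forest(X, y, n_trees: int = 500, mtry=None, seed: int = 0, oob: bool = False) -> RandomForest:
    return RandomForest(n_trees=n_trees, mtry=mtry, seed=seed, oob=oob).fit(X, y)


def predict(model, X) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and class-1 scores (``classes_[1]`` column of predict_proba)."""
    return model.predict(X), model.predict_proba(X)[:, 1]
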