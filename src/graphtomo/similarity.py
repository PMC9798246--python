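"""Relative similarity of feature vectors and template classification.

Two graphs are compared feature by feature with the bounded relative
similarity

    Z_i = 1 - |X_i - Y_i| / max(|X_i|, |Y_i|),      Z_i = 1 if X_i = Y_i = 0,

clamped to [0, 1], and combined into the score

    chi = sum_i w_i Z_i / sum_i w_i          (w_i = 1 by default),

so chi = 1 exactly when all compared features agree and 0 when every
feature is maximally dissimilar. An observable graph is classified by the
control graph with which it scores highest.

The denominator uses absolute values so that sign-carrying features (degree
assortativity can be negative) still yield a score in [0, 1]; with the
magnitudes as printed the textbook form max(X, Y) would exceed the unit
interval for negative or zero features.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin


def feature_similarity(x: float, y: float) -> float:
    """Bounded relative similarity of one feature pair (see module docs)."""
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("features must be finite")
    if x == y:
        return 1.0
    denom = max(abs(x), abs(y))
    if denom == 0.0:
        return 1.0
    return float(np.clip(1.0 - abs(x - y) / denom, 0.0, 1.0))


def similarity_score(X, Y, weights=None) -> float:
    """Weighted mean relative similarity (chi) of two feature vectors."""
    X = np.asarray(X, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    if X.shape != Y.shape:
        raise ValueError("feature vectors must have equal length")
    if weights is None:
        w = np.ones_like(X)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != X.shape:
            raise ValueError("weights must match the feature vectors")
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be nonnegative and not all zero")
    z = np.array([feature_similarity(x, y) for x, y in zip(X, Y)])
    return float(np.dot(w, z) / w.sum())


class SimilarityClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-template classifier under the chi similarity score.

    ``fit`` stores the control (template) feature vectors and their labels;
    ``predict`` assigns each observable feature vector the label of the
    control with the highest chi, ties broken deterministically in favor of
    the control declared first. ``decision_function`` exposes the full chi
    matrix. Follows the sklearn estimator protocol so it composes with
    pipelines and model selection.
    """

    def __init__(self, weights=None):
        self.weights = weights

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n_controls, n_features) matching y")
        if len(set(y.tolist())) != len(y):
            raise ValueError("duplicate control labels")
        self.controls_ = X
        self.classes_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Chi matrix, rows = observables, cols = fitted controls."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with fitted controls")
        return np.array([[similarity_score(row, ctrl, self.weights)
                          for ctrl in self.controls_] for row in X])

    def predict(self, X) -> np.ndarray:
        chi = self.decision_function(X)
        return self.classes_[np.argmax(chi, axis=1)]  # argmax takes first on ties


@dataclass
class SimilarityMatrix:
    """Chi for every (observable, control) pair plus argmax classification."""

    chi: pd.DataFrame  # rows = observable ids, cols = control ids
    predicted: pd.Series  # per observable, the argmax control id
    truth: pd.Series | None = None

    @property
    def accuracy(self) -> float:
        """Fraction of observables whose argmax control is their true label."""
        if self.truth is None:
            raise ValueError("no truth labels supplied")
        return float((self.predicted[self.truth.index] == self.truth).mean())

    @property
    def n_correct(self) -> int:
        if self.truth is None:
            raise ValueError("no truth labels supplied")
        return int((self.predicted[self.truth.index] == self.truth).sum())

    def diagonal(self) -> pd.Series:
        """Chi of each observable against its true control."""
        if self.truth is None:
            raise ValueError("no truth labels supplied")
        return pd.Series(
            {obs: self.chi.loc[obs, ctrl] for obs, ctrl in self.truth.items()})

    def to_report(self) -> dict:
        out = {
            "controls": list(self.chi.columns),
            "observables": list(self.chi.index),
            "predicted": self.predicted.to_dict(),
        }
        if self.truth is not None:
            out["truth"] = self.truth.to_dict()
            out["n_correct"] = self.n_correct
            out["accuracy"] = self.accuracy
            out["diagonal_chi"] = self.diagonal().to_dict()
        return out


def classify(observables: pd.DataFrame, controls: pd.DataFrame,
             truth: dict | None = None, weights=None) -> SimilarityMatrix:
    """Score every observable against every control and classify by argmax.

    ``observables`` and ``controls`` are feature tables indexed by graph id
    (same feature columns, same order). ``truth`` maps observable ids to
    their true control ids; rows without a truth entry are scored but not
    counted in the accuracy.
    """
    if observables.index.has_duplicates or controls.index.has_duplicates:
        raise ValueError("duplicate graph ids")
    if list(observables.columns) != list(controls.columns):
        raise ValueError("observables and controls must share feature columns")
    clf = SimilarityClassifier(weights=weights).fit(
        controls.to_numpy(), controls.index.to_numpy())
    chi = pd.DataFrame(clf.decision_function(observables.to_numpy()),
                       index=observables.index, columns=controls.index)
    predicted = pd.Series(clf.predict(observables.to_numpy()),
                          index=observables.index)
    truth_s = None
    if truth is not None:
        truth_s = pd.Series(truth)
        missing = set(truth_s.index) - set(observables.index)
        if missing:
            raise ValueError(f"truth refers to unknown observables: {missing}")
    return SimilarityMatrix(chi=chi, predicted=predicted, truth=truth_s)
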