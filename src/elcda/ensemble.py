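"""Pair-feature assembly, the five base classifiers and soft-voting fusion.

Per-node embeddings from the three extractors are concatenated into a single
representation F = [F1 || F2 || F3]; a circRNA-disease pair is represented by
[F(c) || F(d)].  Five probabilistic classifiers — an RBF support vector
machine (with Platt-scaled probabilities), a random forest, XGBoost,
LightGBM and Gaussian naive Bayes — are fitted independently and their
positive-class probabilities fused by an unweighted arithmetic mean (soft
voting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

CLASSIFIER_NAMES = ("svm", "rf", "xgb", "lgbm", "gnb")


@dataclass
class EmbeddingSet:
    """Per-node embeddings from one extractor (or their concatenation)."""

    circ: np.ndarray
    disease: np.ndarray
    source: str = "F"

    def __post_init__(self) -> None:
        self.circ = np.asarray(self.circ, dtype=float)
        self.disease = np.asarray(self.disease, dtype=float)
        for name, arr in (("circ", self.circ), ("disease", self.disease)):
            if not np.isfinite(arr).all():
                raise ValueError(f"{self.source} {name} embeddings contain NaN/Inf")


def concat_embeddings(sets: list[EmbeddingSet]) -> EmbeddingSet:
    """F = concat(F1, F2, F3) per node."""
    return EmbeddingSet(
        circ=np.hstack([s.circ for s in sets]),
        disease=np.hstack([s.disease for s in sets]),
        source="F",
    )


def assemble_features(embeddings: EmbeddingSet, pairs: np.ndarray) -> np.ndarray:
    """Row feature per (circRNA index, disease index) pair: [F(c) || F(d)]."""
    pairs = np.asarray(pairs, dtype=int)
    m, n = embeddings.circ.shape[0], embeddings.disease.shape[0]
    for ci, dj in pairs:
        if not 0 <= ci < m:
            raise ValueError(f"circRNA index {ci} has no embedding (m={m})")
        if not 0 <= dj < n:
            raise ValueError(f"disease index {dj} has no embedding (n={n})")
    return np.hstack([embeddings.circ[pairs[:, 0]], embeddings.disease[pairs[:, 1]]])


def soft_vote(probabilities: np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean of per-classifier positive probabilities."""
    P = np.asarray(probabilities, dtype=float)
    if ((P < 0) | (P > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return P.mean(axis=-1)


class SoftVotingAssociationClassifier(BaseEstimator, ClassifierMixin):
    """Soft-voting ensemble of the five base classifiers.

    scikit-learn compatible: ``fit(X, y)`` / ``predict_proba(X)`` on pair
    feature matrices.  ``member_proba`` exposes the per-classifier
    probabilities (SVM, RF, XGBoost, LightGBM, GaussianNB, in that order).
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def _make_members(self):
        rs = self.random_state
        return {
            # Platt-style logistic calibration turns SVM margins into
            # probabilities, fitted on internal training folds
            "svm": make_pipeline(
                StandardScaler(),
                CalibratedClassifierCV(SVC(random_state=rs), ensemble=False)),
            "rf": RandomForestClassifier(random_state=rs),
            "xgb": XGBClassifier(random_state=rs, use_label_encoder=False,
                                 eval_metric="logloss", verbosity=0),
            "lgbm": LGBMClassifier(random_state=rs, verbose=-1),
            "gnb": GaussianNB(),
        }

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        self.classes_ = np.array([0, 1])
        self.members_ = self._make_members()
        for est in self.members_.values():
            est.fit(X, y)
        return self

    def member_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper registers feature names even for
            # plain arrays; the mismatch warning is spurious here
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names")
            cols = [self.members_[name].predict_proba(X)[:, 1]
                    for name in CLASSIFIER_NAMES]
        return np.column_stack(cols)

    def predict_proba(self, X) -> np.ndarray:
        fused = soft_vote(self.member_proba(X))
        return np.column_stack([1.0 - fused, fused])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def prediction_table(circ_ids, disease_ids, pairs, member_probs,
                     labels=None) -> pd.DataFrame:
    """Per-pair classifier and fused probabilities, sorted by fused score."""
    member_probs = np.asarray(member_probs, dtype=float)
    fused = soft_vote(member_probs)
    data = {
        "circRNA": [circ_ids[i] for i, _ in pairs],
        "disease": [disease_ids[j] for _, j in pairs],
    }
    for k, name in enumerate(CLASSIFIER_NAMES):
        data[f"p_{name}"] = member_probs[:, k]
    data["p_fused"] = fused
    if labels is not None:
        data["label"] = np.asarray(labels, dtype=int)
    return pd.DataFrame(data).sort_values("p_fused", ascending=False,
                                          kind="mergesort").reset_index(drop=True)
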