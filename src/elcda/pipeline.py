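"""End-to-end association predictor: three extractors + soft-voting ensemble."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .ensemble import (EmbeddingSet, SoftVotingAssociationClassifier,
                       assemble_features, concat_embeddings)
from .extractors.metapath import MetapathAttentionEncoder
from .extractors.mf import SimilarityRegularizedNMF
from .extractors.sage import GraphSageEncoder
from .hetnet import HeteroNetwork
from .similarity import SimilarityBundle


class AssociationPipeline(BaseEstimator):
    """Fit the three feature extractors and the voting classifier on one
    training split, then score arbitrary circRNA-disease pairs.

    The association matrix used for factorisation and for the GraphSAGE edge
    set is rebuilt from the *training positives only*, so a fitted pipeline
    never sees held-out edges.

    Parameters are dictionaries of keyword overrides for the underlying
    estimators; ``random_state`` seeds all of them (offset per component so
    streams do not collide).
    """

    def __init__(self, metapath_params: dict | None = None,
                 mf_params: dict | None = None,
                 sage_params: dict | None = None,
                 use_extractors: tuple[str, ...] = ("metapath", "mf", "sage"),
                 random_state: int = 0):
        self.metapath_params = metapath_params
        self.mf_params = mf_params
        self.sage_params = sage_params
        self.use_extractors = use_extractors
        self.random_state = random_state

    def fit(self, net: HeteroNetwork, bundle: SimilarityBundle,
            pairs: np.ndarray, y: np.ndarray):
        pairs = np.asarray(pairs, dtype=int)
        y = np.asarray(y, dtype=int)
        m, n = net.n_circ, net.n_disease

        # association matrix restricted to training positives
        H = np.zeros((m, n))
        for (ci, dj), label in zip(pairs, y):
            if label == 1:
                H[ci, dj] = 1.0
        net_train = net.with_cd(H.astype(int))

        sets: list[EmbeddingSet] = []
        if "metapath" in self.use_extractors:
            self.metapath_ = MetapathAttentionEncoder(
                random_state=self.random_state,
                **(self.metapath_params or {}))
            self.metapath_.fit(net_train, bundle, pairs, y)
            sets.append(EmbeddingSet(self.metapath_.circ_embeddings_,
                                     self.metapath_.disease_embeddings_, "F1"))
        if "mf" in self.use_extractors:
            W = np.zeros((m, n))
            W[pairs[:, 0], pairs[:, 1]] = 1.0  # observed training cells
            self.mf_ = SimilarityRegularizedNMF(
                random_state=self.random_state + 1, **(self.mf_params or {}))
            self.mf_.fit(H, W=W, SC=bundle.SC, SD=bundle.SD)
            sets.append(EmbeddingSet(self.mf_.C_, self.mf_.D_, "F2"))
        if "sage" in self.use_extractors:
            self.sage_ = GraphSageEncoder(
                random_state=self.random_state + 2, **(self.sage_params or {}))
            self.sage_.fit(net_train, bundle, pairs, y)
            sets.append(EmbeddingSet(self.sage_.circ_embeddings_,
                                     self.sage_.disease_embeddings_, "F3"))
        if not sets:
            raise ValueError("at least one extractor must be enabled")

        self.embeddings_ = concat_embeddings(sets)
        X = assemble_features(self.embeddings_, pairs)
        self.classifier_ = SoftVotingAssociationClassifier(
            random_state=self.random_state + 3)
        self.classifier_.fit(X, y)
        return self

    def member_proba(self, pairs: np.ndarray) -> np.ndarray:
        X = assemble_features(self.embeddings_, np.asarray(pairs, dtype=int))
        return self.classifier_.member_proba(X)

    def predict_proba(self, pairs: np.ndarray) -> np.ndarray:
        return self.classifier_.predict_proba(
            assemble_features(self.embeddings_, np.asarray(pairs, dtype=int)))

    def score_all_pairs(self) -> np.ndarray:
        """Fused probability for every (circRNA, disease) cell."""
        m = self.embeddings_.circ.shape[0]
        n = self.embeddings_.disease.shape[0]
        pairs = np.array([(i, j) for i in range(m) for j in range(n)])
        return self.predict_proba(pairs)[:, 1].reshape(m, n)
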