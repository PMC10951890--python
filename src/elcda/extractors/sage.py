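"""GraphSAGE-style feature extractor (local, nonlinear features).

Nodes of the union graph (training circRNA-disease edges plus all
circRNA-miRNA and miRNA-disease edges) carry their integrated-similarity
rows as input features, projected per type into a shared space.  Each layer
draws a fixed-size neighbour sample — without replacement when the degree
covers the fan-out, with replacement otherwise, and the node itself when it
is isolated — and applies a mean aggregation followed by a learned affine
map and nonlinearity:

    h_v <- sigma(W * MEAN({h_v} U {h_u : u sampled}))

Training reuses the logistic inner-product link score with binary
cross-entropy on the training pairs.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .._autograd import Adam, Tensor
from ..hetnet import HeteroNetwork

_EPS = 1e-12


def sample_neighbors(neighbors: np.ndarray, v: int, s: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Fixed-size neighbour sample for one node.

    Degree >= s: uniform subset without replacement; 0 < degree < s: draws
    with replacement up to size s; isolated nodes return themselves s times.
    """
    if s < 1:
        raise ValueError("sample size must be >= 1")
    neighbors = np.asarray(neighbors)
    if neighbors.size == 0:
        return np.full(s, v)
    if neighbors.size >= s:
        return rng.choice(neighbors, size=s, replace=False)
    return rng.choice(neighbors, size=s, replace=True)


def sage_layer(h_v: np.ndarray, sampled: np.ndarray, W: np.ndarray,
               sigma=None) -> np.ndarray:
    """Single-node mean-aggregator layer (numpy forward; oracle in tests)."""
    h_v = np.asarray(h_v, dtype=float)
    sampled = np.asarray(sampled, dtype=float)
    stack = np.vstack([h_v[None, :], sampled]) if sampled.size else h_v[None, :]
    agg = W @ stack.mean(axis=0)
    return sigma(agg) if sigma is not None else agg


class GraphSageEncoder(BaseEstimator):
    """GraphSAGE embeddings for circRNAs and diseases (feature set F3).

    Parameters
    ----------
    embed_dim : width of the projected/hidden node space.
    depth : number of aggregation layers L.
    fanouts : per-layer neighbour sample sizes (length == depth).
    epochs, lr : Adam schedule for the link BCE loss; neighbourhoods are
        resampled each epoch from an epoch-derived seed.
    random_state : seeds initialisation and neighbour sampling.

    Attributes
    ----------
    circ_embeddings_, disease_embeddings_ : final-layer embeddings.
    loss_history_ : BCE per epoch.
    """

    def __init__(self, embed_dim: int = 64, depth: int = 2,
                 fanouts: tuple[int, ...] = (10, 10), epochs: int = 150,
                 lr: float = 5e-3, random_state: int = 0):
        self.embed_dim = embed_dim
        self.depth = depth
        self.fanouts = fanouts
        self.epochs = epochs
        self.lr = lr
        self.random_state = random_state

    @staticmethod
    def _adjacency_lists(net: HeteroNetwork) -> list[np.ndarray]:
        """Undirected union graph over global indices (C, then M, then D)."""
        m, p, n = net.n_circ, net.n_mirna, net.n_disease
        adj: list[list[int]] = [[] for _ in range(m + p + n)]
        def link(a, b):
            adj[a].append(b)
            adj[b].append(a)
        for i, j in zip(*np.nonzero(net.A_CD)):
            link(int(i), m + p + int(j))
        for i, j in zip(*np.nonzero(net.A_CM)):
            link(int(i), m + int(j))
        for i, j in zip(*np.nonzero(net.A_MD)):
            link(m + int(i), m + p + int(j))
        return [np.asarray(sorted(set(x)), dtype=int) for x in adj]

    def _averaging_matrices(self, adj: list[np.ndarray],
                            rng: np.random.Generator) -> list[np.ndarray]:
        """One (N, N) mean-aggregation matrix per layer for this epoch."""
        if len(self.fanouts) != self.depth:
            raise ValueError("fanouts must provide one sample size per layer")
        N = len(adj)
        mats = []
        for s in self.fanouts:
            A = np.zeros((N, N))
            for v in range(N):
                sampled = sample_neighbors(adj[v], v, s, rng)
                A[v, v] += 1.0
                for u in sampled:
                    A[v, u] += 1.0
                A[v] /= s + 1
            mats.append(A)
        return mats

    def _forward(self, params, feats, avg_mats):
        H = Tensor.concat([Tensor(feats["C"]) @ params["W_c"],
                           Tensor(feats["M"]) @ params["W_m"],
                           Tensor(feats["D"]) @ params["W_d"]], axis=0)
        for ell, A in enumerate(avg_mats):
            H = ((Tensor(A) @ H) @ params[f"W_{ell}"]).elu()
        return H

    def fit(self, net: HeteroNetwork, bundle, pairs: np.ndarray, y: np.ndarray):
        pairs = np.asarray(pairs, dtype=int)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.random_state)
        l = self.embed_dim
        m, p, n = net.n_circ, net.n_mirna, net.n_disease

        def init(*shape):
            return Tensor(rng.standard_normal(shape) / np.sqrt(shape[-1]),
                          requires_grad=True)

        params = {"W_c": init(m, l), "W_m": init(p, l), "W_d": init(n, l)}
        for ell in range(self.depth):
            params[f"W_{ell}"] = init(l, l)

        feats = {"C": np.asarray(bundle.SC, dtype=float),
                 "M": np.asarray(bundle.SM, dtype=float),
                 "D": np.asarray(bundle.SD, dtype=float)}
        adj = self._adjacency_lists(net)
        opt = Adam(list(params.values()), lr=self.lr)
        ci, dj = pairs[:, 0], m + p + pairs[:, 1]
        losses = []
        for epoch in range(self.epochs):
            epoch_rng = np.random.default_rng(rng.integers(2 ** 31))
            avg_mats = self._averaging_matrices(adj, epoch_rng)
            opt.zero_grad()
            H = self._forward(params, feats, avg_mats)
            score = (H.take(ci) * H.take(dj)).sum(axis=1)
            prob = score.sigmoid()
            loss = -((prob + _EPS).log() * y + (1.0 - prob + _EPS).log() * (1.0 - y)).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged: loss {loss.data} at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        final_rng = np.random.default_rng(self.random_state + 1)
        H = self._forward(params, feats, self._averaging_matrices(adj, final_rng))
        self.circ_embeddings_ = H.data[:m].copy()
        self.disease_embeddings_ = H.data[m + p:].copy()
        self.loss_history_ = np.asarray(losses)
        self.params_ = params
        return self
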