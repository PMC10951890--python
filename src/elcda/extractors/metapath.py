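"""Metapath-attention feature extractor (global, substructural features).

Nodes are first projected into a shared l-dimensional space by type-specific
linear maps applied to their integrated-similarity rows.  For every symmetric
metapath anchored at a node, each metapath instance (walk) is encoded into a
single vector (mean of the projected features of its nodes by default); a
multi-head additive attention aggregates the instances of one metapath, and a
second attention level fuses the per-metapath vectors across the node type's
metapaths.  The whole stack is trained end to end on link labels with a
logistic inner-product score and binary cross-entropy.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .._autograd import Adam, Tensor, masked_softmax
from ..hetnet import CIRC_METAPATHS, DISEASE_METAPATHS, HeteroNetwork, Metapath

_EPS = 1e-12


# ---------------------------------------------------------------------------
# functional pieces (numpy forward passes; also serve as oracles in tests)


def project_features(S: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Project similarity rows into the shared space: h' = S @ W^T."""
    S, W = np.asarray(S, dtype=float), np.asarray(W, dtype=float)
    if S.shape[-1] != W.shape[1]:
        raise ValueError(f"feature length {S.shape[-1]} does not match W {W.shape}")
    return S @ W.T

def _suffix_counts(net: HeteroNetwork, path: Metapath) -> list[np.ndarray]:
    """counts[k][v] = number of path completions from node v at position k."""
    seq = path.type_sequence
    sizes = {"C": net.n_circ, "M": net.n_mirna, "D": net.n_disease}
    counts = [np.ones(sizes[seq[-1]], dtype=np.int64)]
    for a, b in reversed(list(zip(seq, seq[1:]))):
        counts.append(net.adjacency(a, b) @ counts[-1])
    counts.reverse()
    return counts


def _unrank_walk(net: HeteroNetwork, path: Metapath, anchor: int,
                 rank: int, counts: list[np.ndarray]) -> tuple[int, ...]:
    """The rank-th walk (in lexicographic neighbour order) anchored at a node."""
    seq = path.type_sequence
    walk = [anchor]
    node = anchor
    for k, (a, b) in enumerate(zip(seq, seq[1:])):
        row = net.adjacency(a, b)[node]
        neighbours = np.nonzero(row)[0]
        for nb in neighbours:
            c = int(counts[k + 1][nb])
            if rank < c:
                node = int(nb)
                break
            rank -= c
        walk.append(node)
    return tuple(walk)


def enumerate_instances(net: HeteroNetwork, path: Metapath | str, anchor: int,
                        cap: int | None = None, seed: int = 0) -> list[tuple[int, ...]]:
    """All metapath instances anchored at a node, or a seeded uniform subset.

    Instances are walks (node index tuples, indices local to each type) that
    follow the path's type sequence starting at ``anchor``.  When the count
    exceeds ``cap`` a uniform subset without replacement is drawn by unranking
    seeded random ranks, so no exhaustive enumeration is ever materialised.
    """
    if isinstance(path, str):
        path = Metapath.parse(path)
    counts = _suffix_counts(net, path)
    total = int(counts[0][anchor])
    if total == 0:
        return []
    if cap is None or total <= cap:
        ranks = np.arange(total)
    else:
        rng = np.random.default_rng(seed)
        ranks = np.sort(rng.choice(total, size=cap, replace=False))
    return [_unrank_walk(net, path, anchor, int(r), counts) for r in ranks]


def encode_instance(instance_vectors: np.ndarray) -> np.ndarray:
    """Default metapath instance encoder: elementwise mean of node vectors."""
    vecs = np.asarray(instance_vectors, dtype=float)
    if vecs.ndim != 2 or vecs.shape[0] == 0:
        raise ValueError("an instance must contain at least one projected node")
    return vecs.mean(axis=0)


def _leaky_relu(x: np.ndarray, slope: float = 0.01) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(x))


def intra_metapath_attention(anchor_vec: np.ndarray, instance_encodings: np.ndarray,
                             alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-head instance attention: returns (weights, aggregated vector).

    e_i = LeakyReLU(alpha^T [h'_anchor || enc_i]); weights = softmax(e);
    output = ELU(sum_i weights_i * enc_i).  With no instances the output is
    the zero vector.
    """
    enc = np.asarray(instance_encodings, dtype=float)
    l = len(anchor_vec)
    if enc.shape[0] == 0:
        return np.zeros(0), np.zeros(l)
    e = _leaky_relu(enc @ alpha[l:] + float(anchor_vec @ alpha[:l]))
    e = e - e.max()
    w = np.exp(e) / np.exp(e).sum()
    return w, _elu(w @ enc)


def inter_metapath_attention(per_path_vectors: list[np.ndarray], W_v: np.ndarray,
                             b_v: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fuse per-metapath node matrices: returns (beta weights, fused matrix).

    s_p = mean over the type's nodes of tanh(W_v h_p + b_v); e_p = q^T s_p;
    beta = softmax(e); fused = sum_p beta_p * h_p.
    """
    e = np.array([q @ np.tanh(h @ W_v.T + b_v).mean(axis=0) for h in per_path_vectors])
    e = e - e.max()
    beta = np.exp(e) / np.exp(e).sum()
    fused = sum(b * h for b, h in zip(beta, per_path_vectors))
    return beta, fused


# ---------------------------------------------------------------------------
# trainable extractor


class MetapathAttentionEncoder(BaseEstimator):
    """Metapath-attention embeddings for circRNAs and diseases (feature set F1).

    Parameters
    ----------
    embed_dim : dimension l of the projected node space.
    heads : number K of attention heads (per-metapath outputs are the
        concatenation of the K head outputs, so embeddings have K*l columns).
    encoder : 'mean' or 'linear' metapath instance encoder.
    instance_cap : per anchor and metapath, at most this many instances are
        used (uniform seeded subset).
    epochs, lr : Adam training schedule for the link BCE loss.
    random_state : seeds initialisation and instance subsampling.

    Attributes
    ----------
    circ_embeddings_, disease_embeddings_ : (m, K*l) and (n, K*l) arrays.
    loss_history_ : BCE per epoch.
    """

    def __init__(self, embed_dim: int = 64, heads: int = 8, encoder: str = "mean",
                 instance_cap: int = 32, epochs: int = 200, lr: float = 1e-3,
                 circ_metapaths: tuple[str, ...] = CIRC_METAPATHS,
                 disease_metapaths: tuple[str, ...] = DISEASE_METAPATHS,
                 random_state: int = 0):
        self.embed_dim = embed_dim
        self.heads = heads
        self.encoder = encoder
        self.instance_cap = instance_cap
        self.epochs = epochs
        self.lr = lr
        self.circ_metapaths = circ_metapaths
        self.disease_metapaths = disease_metapaths
        self.random_state = random_state

    # -- constant structure ------------------------------------------------

    def _instance_tables(self, net: HeteroNetwork, rng: np.random.Generator):
        """Precompute, per metapath, the padded instance-averaging tensors.

        For each metapath an (n_anchor * cap, N_total) averaging matrix maps
        the stacked projected node matrix to padded instance encodings, plus
        a boolean validity mask (n_anchor, cap).
        """
        m, p, n = net.n_circ, net.n_mirna, net.n_disease
        offset = {"C": 0, "M": m, "D": m + p}
        total = m + p + n
        tables = {}
        for spec_ in (*self.circ_metapaths, *self.disease_metapaths):
            path = Metapath.parse(spec_)
            anchor_type = path.type_sequence[0]
            n_anchor = {"C": m, "M": p, "D": n}[anchor_type]
            cap = self.instance_cap
            avg = np.zeros((n_anchor * cap, total))
            mask = np.zeros((n_anchor, cap), dtype=bool)
            plen = len(path.type_sequence)
            for a in range(n_anchor):
                seed = int(rng.integers(2 ** 31))
                inst = enumerate_instances(net, path, a, cap=cap, seed=seed)
                for k, walk in enumerate(inst):
                    mask[a, k] = True
                    row = avg[a * cap + k]
                    for t, node in zip(path.type_sequence, walk):
                        row[offset[t] + node] += 1.0 / plen
            tables[spec_] = (avg, mask, anchor_type)
        return tables

    # -- forward pass ------------------------------------------------------

    def _forward(self, params, consts):
        Hall = Tensor.concat([consts["SC"] @ params["W_c"],
                              consts["SM"] @ params["W_m"],
                              consts["SD"] @ params["W_d"]], axis=0)
        if self.encoder == "linear":
            Henc = (Hall @ params["W_enc"]).elu()
        else:
            Henc = Hall
        l, K = self.embed_dim, self.heads
        out = {}
        for node_type, paths in (("C", self.circ_metapaths), ("D", self.disease_metapaths)):
            anchors = consts[f"anchor_rows_{node_type}"] @ Hall
            per_path = []
            for spec_ in paths:
                avg, mask, _ = consts["tables"][spec_]
                n_anchor, cap = mask.shape
                enc = (avg @ Henc).reshape(n_anchor, cap, l)
                # all K heads at once: alpha is (2l, K), split into the
                # anchor half a1 and the instance half a2
                alpha = params[f"alpha_{spec_}"]
                a1 = alpha.take(np.arange(l), axis=0)
                a2 = alpha.take(np.arange(l, 2 * l), axis=0)
                e = ((anchors @ a1).reshape(n_anchor, 1, K)
                     + Tensor.einsum("acl,lk->ack", "ack,lk->acl", "acl,ack->lk",
                                     enc, a2)).leaky_relu()
                w = masked_softmax(e, mask[:, :, None], axis=1)
                agg = Tensor.einsum("ack,acl->akl", "akl,acl->ack", "ack,akl->acl",
                                    w, enc).reshape(n_anchor, K * l).elu()
                per_path.append(agg)
            W_v, b_v, q = (params[f"Wv_{node_type}"], params[f"bv_{node_type}"],
                           params[f"q_{node_type}"])
            summaries = [ (h @ W_v + b_v).tanh().mean(axis=0) for h in per_path]
            e_p = Tensor.concat([(s * q).sum().reshape(1) for s in summaries], axis=0)
            beta = masked_softmax(e_p, np.ones(len(per_path), dtype=bool), axis=0)
            fused = per_path[0] * beta.take([0]).reshape(1, 1)
            for i in range(1, len(per_path)):
                fused = fused + per_path[i] * beta.take([i]).reshape(1, 1)
            out[node_type] = fused
        return out["C"], out["D"]

    # -- training ----------------------------------------------------------

    def fit(self, net: HeteroNetwork, bundle, pairs: np.ndarray, y: np.ndarray):
        pairs = np.asarray(pairs, dtype=int)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.random_state)
        l, K = self.embed_dim, self.heads
        m, p, n = net.n_circ, net.n_mirna, net.n_disease

        def init(*shape):
            fan = shape[-1]
            return Tensor(rng.standard_normal(shape) / np.sqrt(fan), requires_grad=True)

        params = {"W_c": init(m, l), "W_m": init(p, l), "W_d": init(n, l)}
        if self.encoder == "linear":
            params["W_enc"] = init(l, l)
        for spec_ in (*self.circ_metapaths, *self.disease_metapaths):
            params[f"alpha_{spec_}"] = init(2 * l, K)
        for t in ("C", "D"):
            params[f"Wv_{t}"] = init(K * l, l)
            params[f"bv_{t}"] = Tensor(np.zeros(l), requires_grad=True)
            params[f"q_{t}"] = init(l)

        anchor_C = np.eye(m + p + n)[:m]
        anchor_D = np.eye(m + p + n)[m + p:]
        consts = {
            "SC": np.asarray(bundle.SC, dtype=float),
            "SM": np.asarray(bundle.SM, dtype=float),
            "SD": np.asarray(bundle.SD, dtype=float),
            "tables": self._instance_tables(net, rng),
            "anchor_rows_C": anchor_C,
            "anchor_rows_D": anchor_D,
        }

        opt = Adam(list(params.values()), lr=self.lr)
        ci, dj = pairs[:, 0], pairs[:, 1]
        losses = []
        for _ in range(self.epochs):
            opt.zero_grad()
            h_c, h_d = self._forward(params, consts)
            score = (h_c.take(ci) * h_d.take(dj)).sum(axis=1)
            prob = score.sigmoid()
            loss = -((prob + _EPS).log() * y + (1.0 - prob + _EPS).log() * (1.0 - y)).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged: loss {loss.data} at epoch {len(losses)}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        h_c, h_d = self._forward(params, consts)
        self.circ_embeddings_ = h_c.data.copy()
        self.disease_embeddings_ = h_d.data.copy()
        self.loss_history_ = np.asarray(losses)
        self.params_ = params
        return self
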