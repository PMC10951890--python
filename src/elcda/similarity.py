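"""Multi-view similarity measures for circRNAs and diseases.

Disease side: MeSH-style DAG semantic similarity (Wang measure), Gaussian
interaction profile (GIP) kernel over miRNA-disease interaction columns, and
metapath similarities (PathSim, HeteSim).  circRNA side: Spearman expression
similarity, functional similarity via best-match averaging over associated
disease sets, and the same metapath similarities.  The integrated matrices

    SD = 0.5*SD_bio + 0.25*HeteSim_D + 0.25*PathSim_D
    SC = 0.5*SC_bio + 0.25*HeteSim_C + 0.25*PathSim_C

are the node features consumed by every feature extractor.  The HeteSim and
PathSim terms average over that node type's symmetric metapaths (CDC, CMC,
CDMDC, CMDMC for circRNAs; DCD, DMD, DCMCD, DMCMD for diseases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .hetnet import CIRC_METAPATHS, DISEASE_METAPATHS, HeteroNetwork, Metapath, metapath_adjacency


# ---------------------------------------------------------------------------
# input containers


@dataclass
class DiseaseDAG:
    """Rooted disease ontology given as child -> parent edges.

    ``delta`` is the semantic contribution decay per hop (0 < delta < 1).
    """

    parent_edges: list[tuple[str, str]]
    delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie in (0, 1)")
        g = nx.DiGraph()
        for child, parent in self.parent_edges:
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("parent edges contain a cycle")
        self._graph = g

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    def ancestors_closure(self, d: str) -> set[str]:
        """T(d): the disease itself plus every ancestor reachable via parents."""
        return {d} | nx.descendants(self._graph, d)

    def parents(self, d: str) -> set[str]:
        return set(self._graph.successors(d))


@dataclass
class ExpressionProfiles:
    """Normalised expression profiles for a subset of circRNAs (rows)."""

    circ_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if len(set(self.circ_ids)) != len(self.circ_ids):
            raise ValueError("duplicate circRNA identifier in expression profiles")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.circ_ids):
            raise ValueError("profile matrix rows must match circ_ids")
        if self.matrix.shape[1] < 3:
            raise ValueError("need at least 3 samples for rank correlation")


@dataclass
class SimilarityBundle:
    """All intermediate and integrated similarity matrices."""

    SS: np.ndarray
    GD: np.ndarray
    SD_bio: np.ndarray
    SE: np.ndarray
    SF: np.ndarray
    SC_bio: np.ndarray
    pathsim_C: np.ndarray
    hetesim_C: np.ndarray
    pathsim_D: np.ndarray
    hetesim_D: np.ndarray
    SC: np.ndarray
    SD: np.ndarray
    SM: np.ndarray  # miRNA GIP similarity, used as miRNA node features


@dataclass
class SimilarityConfig:
    delta: float = 0.5
    integration_weights: tuple[float, float, float] = (0.5, 0.25, 0.25)
    circ_metapaths: tuple[str, ...] = CIRC_METAPATHS
    disease_metapaths: tuple[str, ...] = DISEASE_METAPATHS

    def __post_init__(self) -> None:
        if abs(sum(self.integration_weights) - 1.0) > 1e-12:
            raise ValueError("integration weights must sum to 1")
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie in (0, 1)")


# ---------------------------------------------------------------------------
# metapath similarities


def transition_matrix(A: np.ndarray) -> np.ndarray:
    """Row-stochastic transition matrix; all-zero rows stay all-zero."""
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("adjacency matrix must be nonnegative")
    sums = A.sum(axis=1, keepdims=True)
    out = np.divide(A, sums, out=np.zeros_like(A), where=sums > 0)
    return out


def pathsim(net: HeteroNetwork, path: Metapath | str) -> np.ndarray:
    """PathSim: 2*M[x,y] / (M[x,x] + M[y,y]) from metapath instance counts."""
    if isinstance(path, str):
        path = Metapath.parse(path)
    if not path.is_palindromic:
        raise ValueError(f"PathSim requires a palindromic metapath, got {path}")
    M = metapath_adjacency(net, path).astype(float)
    diag = np.diag(M)
    denom = diag[:, None] + diag[None, :]
    return np.divide(2.0 * M, denom, out=np.zeros_like(M), where=denom > 0)


def _half_transition(net: HeteroNetwork, types: tuple[str, ...]) -> np.ndarray:
    T = transition_matrix(net.adjacency(types[0], types[1]))
    for a, b in zip(types[1:], types[2:]):
        T = T @ transition_matrix(net.adjacency(a, b))
    return T


def hetesim(net: HeteroNetwork, path: Metapath | str) -> np.ndarray:
    """Simplified HeteSim: cosine between rows of the half-path transition matrix.

    The palindromic path is split at its middle node type; the probability of
    reaching each middle node from an endpoint is the chained product of
    row-normalised transition matrices, and similarity is the cosine of those
    reach vectors.  Rows with zero reach give similarity 0.
    """
    if isinstance(path, str):
        path = Metapath.parse(path)
    if path.edge_count % 2 != 0:
        raise ValueError(
            f"HeteSim needs an even number of edges to split at a middle node "
            f"type; {path} has {path.edge_count} (all standard metapaths — "
            f"CDC, CMC, CDMDC, CMDMC, DCD, DMD, DCMCD, DMCMD — are even)")
    if not path.is_palindromic:
        raise ValueError(f"HeteSim requires a palindromic metapath, got {path}")
    mid = path.edge_count // 2
    left = path.type_sequence[: mid + 1]
    T = _half_transition(net, left)
    norms = np.linalg.norm(T, axis=1)
    denom = norms[:, None] * norms[None, :]
    return np.divide(T @ T.T, denom, out=np.zeros_like(denom), where=denom > 0)


def _mean_metapath_similarity(net: HeteroNetwork, paths, fn) -> np.ndarray:
    mats = [fn(net, p) for p in paths]
    return np.mean(mats, axis=0)


# ---------------------------------------------------------------------------
# disease semantic similarity (Wang measure)


def semantic_contribution(dag: DiseaseDAG, d_i: str) -> dict[str, float]:
    """Semantic contribution of every ancestor of ``d_i`` (itself included).

    The disease contributes 1 to itself; each ancestor contributes
    ``delta ** hops`` along its best (max) path toward the disease.
    """
    if d_i not in dag.nodes:
        raise ValueError(f"disease {d_i!r} not present in the DAG")
    closure = dag.ancestors_closure(d_i)
    sub = dag._graph.subgraph(closure)
    scores: dict[str, float] = {d_i: 1.0}
    # child->parent edges: topological order visits children before parents
    for node in nx.topological_sort(sub):
        if node not in scores:
            continue
        for parent in sub.successors(node):
            cand = dag.delta * scores[node]
            if cand > scores.get(parent, 0.0):
                scores[parent] = cand
    return scores


def disease_semantic_similarity(
    dag: DiseaseDAG, disease_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Semantic similarity matrix over ``disease_ids`` plus a coverage mask.

    SS(d_i, d_j) sums the contributions of shared ancestors from both sides,
    normalised by the two semantic values DV(d_i) + DV(d_j).  The mask marks
    pairs where both diseases appear in the DAG; uncovered entries are 0.
    """
    n = len(disease_ids)
    SS = np.zeros((n, n))
    cov = np.zeros((n, n), dtype=bool)
    in_dag = [d for d in disease_ids if d in dag.nodes]
    contrib = {d: semantic_contribution(dag, d) for d in in_dag}
    dv = {d: sum(contrib[d].values()) for d in in_dag}
    index = {d: i for i, d in enumerate(disease_ids)}
    for a in in_dag:
        for b in in_dag:
            i, j = index[a], index[b]
            cov[i, j] = True
            shared = contrib[a].keys() & contrib[b].keys()
            num = sum(contrib[a][t] + contrib[b][t] for t in shared)
            SS[i, j] = num / (dv[a] + dv[b])
    return SS, cov


# ---------------------------------------------------------------------------
# kernel, expression and functional similarities


def gip_kernel(MD: np.ndarray) -> np.ndarray:
    """Disease GIP kernel over the columns of the miRNA-disease matrix.

    Bandwidth beta = n / sum_i ||MD[:, i]||^2.  If every profile is empty the
    bandwidth is undefined; the kernel falls back to the identity (zero
    similarity off-diagonal, 1 on the diagonal).
    """
    MD = np.asarray(MD)
    if not np.isin(MD, (0, 1)).all():
        raise ValueError("interaction profile matrix must be binary")
    MD = MD.astype(float)
    n = MD.shape[1]
    total = (MD ** 2).sum()
    if total == 0:
        return np.eye(n)
    beta = n / total
    sq = (MD ** 2).sum(axis=0)
    d2 = sq[:, None] + sq[None, :] - 2.0 * MD.T @ MD
    np.maximum(d2, 0.0, out=d2)
    G = np.exp(-beta * d2)
    np.fill_diagonal(G, 1.0)
    return G


def gip_kernel_rows(A: np.ndarray) -> np.ndarray:
    """GIP kernel over the rows of a binary interaction matrix."""
    return gip_kernel(np.asarray(A).T)


def disease_bio_similarity(SS: np.ndarray, GD: np.ndarray, coverage: np.ndarray) -> np.ndarray:
    """Semantic similarity where defined, GIP kernel similarity otherwise."""
    SS, GD, coverage = np.asarray(SS), np.asarray(GD), np.asarray(coverage, dtype=bool)
    if not SS.shape == GD.shape == coverage.shape:
        raise ValueError("SS, GD and coverage must share a shape")
    return np.where(coverage, SS, GD)


def expression_similarity(
    profiles: ExpressionProfiles, circ_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rank correlation between expression profiles.

    Returns an m x m matrix over ``circ_ids`` plus a coverage mask that is
    true only where both circRNAs are profiled and neither profile is
    constant (a constant profile has no defined rank correlation; those
    pairs are set to 0 and left uncovered).
    """
    m = len(circ_ids)
    SE = np.zeros((m, m))
    cov = np.zeros((m, m), dtype=bool)
    pos = {c: i for i, c in enumerate(circ_ids)}
    rows = [i for i, c in enumerate(profiles.circ_ids) if c in pos]
    if not rows:
        return SE, cov
    X = profiles.matrix[rows]
    idx = np.array([pos[profiles.circ_ids[i]] for i in rows])
    constant = np.ptp(X, axis=1) == 0
    ranks = np.apply_along_axis(rankdata, 1, X)
    centred = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    denom = norms[:, None] * norms[None, :]
    corr = np.divide(centred @ centred.T, denom, out=np.zeros_like(denom), where=denom > 0)
    ok = ~constant
    corr[~ok, :] = 0.0
    corr[:, ~ok] = 0.0
    np.fill_diagonal(corr, np.where(ok, 1.0, 0.0))
    SE[np.ix_(idx, idx)] = corr
    cov[np.ix_(idx, idx)] = np.outer(ok, ok)
    return SE, cov


def functional_similarity(SD: np.ndarray, A_CD: np.ndarray) -> np.ndarray:
    """circRNA functional similarity by best-match averaging of disease sets.

    With N(c) the disease set of circRNA c, each disease of one circRNA is
    matched to its most similar disease in the other circRNA's set, and the
    matches from both sides are averaged.  circRNAs without diseases get a
    zero row apart from the unit diagonal.
    """
    SD = np.asarray(SD, dtype=float)
    A_CD = np.asarray(A_CD)
    m = A_CD.shape[0]
    sets = [np.nonzero(A_CD[i])[0] for i in range(m)]
    # best[j][d] = max_{d' in N(c_j)} SD[d, d']
    best = [SD[:, s].max(axis=1) if s.size else None for s in sets]
    SF = np.zeros((m, m))
    for i in range(m):
        Ni = sets[i]
        if Ni.size == 0:
            continue
        for j in range(i, m):
            Nj = sets[j]
            if Nj.size == 0:
                continue
            val = (best[j][Ni].sum() + best[i][Nj].sum()) / (Ni.size + Nj.size)
            SF[i, j] = SF[j, i] = val
    np.fill_diagonal(SF, 1.0)
    return SF


def circ_bio_similarity(SF: np.ndarray, SE: np.ndarray, coverage: np.ndarray) -> np.ndarray:
    """0.5*(SF + SE) where expression similarity exists, SF otherwise."""
    SF, SE, coverage = np.asarray(SF), np.asarray(SE), np.asarray(coverage, dtype=bool)
    if not SF.shape == SE.shape == coverage.shape:
        raise ValueError("SF, SE and coverage must share a shape")
    return np.where(coverage, 0.5 * (SF + SE), SF)


def integrate_similarity(
    bio: np.ndarray,
    het: np.ndarray,
    path: np.ndarray,
    weights: tuple[float, float, float] = (0.5, 0.25, 0.25),
) -> np.ndarray:
    """Convex combination of biological, HeteSim and PathSim similarity."""
    bio, het, path = (np.asarray(x, dtype=float) for x in (bio, het, path))
    if not bio.shape == het.shape == path.shape:
        raise ValueError("similarity matrices must share a shape")
    if abs(sum(weights) - 1.0) > 1e-12:
        raise ValueError("integration weights must sum to 1")
    return weights[0] * bio + weights[1] * het + weights[2] * path


# ---------------------------------------------------------------------------
# full bundle


def compute_similarity_bundle(
    net: HeteroNetwork,
    dag: DiseaseDAG | None = None,
    profiles: ExpressionProfiles | None = None,
    config: SimilarityConfig | None = None,
) -> SimilarityBundle:
    """Compute every similarity matrix and the integrated SC and SD.

    The DAG and expression profiles are optional; without them the
    biological layers fall back to GIP (diseases) and functional similarity
    (circRNAs) alone, exactly as the coverage-mask combination rules imply.
    """
    cfg = config or SimilarityConfig()
    m, n = net.n_circ, net.n_disease

    if dag is not None:
        dag = DiseaseDAG(dag.parent_edges, delta=cfg.delta)
        SS, cov_ss = disease_semantic_similarity(dag, net.disease_ids)
    else:
        SS, cov_ss = np.zeros((n, n)), np.zeros((n, n), dtype=bool)
    GD = gip_kernel(net.A_MD)
    SD_bio = disease_bio_similarity(SS, GD, cov_ss)

    hetesim_D = _mean_metapath_similarity(net, cfg.disease_metapaths, hetesim)
    pathsim_D = _mean_metapath_similarity(net, cfg.disease_metapaths, pathsim)
    SD = integrate_similarity(SD_bio, hetesim_D, pathsim_D, cfg.integration_weights)

    if profiles is not None:
        SE, cov_se = expression_similarity(profiles, net.circ_ids)
    else:
        SE, cov_se = np.zeros((m, m)), np.zeros((m, m), dtype=bool)
    SF = functional_similarity(SD, net.A_CD)
    SC_bio = circ_bio_similarity(SF, SE, cov_se)

    hetesim_C = _mean_metapath_similarity(net, cfg.circ_metapaths, hetesim)
    pathsim_C = _mean_metapath_similarity(net, cfg.circ_metapaths, pathsim)
    SC = integrate_similarity(SC_bio, hetesim_C, pathsim_C, cfg.integration_weights)

    SM = gip_kernel_rows(net.A_MD)

    return SimilarityBundle(
        SS=SS, GD=GD, SD_bio=SD_bio, SE=SE, SF=SF, SC_bio=SC_bio,
        pathsim_C=pathsim_C, hetesim_C=hetesim_C,
        pathsim_D=pathsim_D, hetesim_D=hetesim_D,
        SC=SC, SD=SD, SM=SM,
    )
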