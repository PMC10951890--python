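"""Synthetic fixtures: the worked-example toy network and planted-structure
heterogeneous networks.

``figure3_toy`` reproduces the small bipartite graph used to illustrate
PathSim and HeteSim (5 circRNAs, 3 diseases, c2 linked to {d1, d2} and c4 to
{d1, d2, d3}).  ``simulate_hetnet`` draws a sparse tri-partite binary network
whose three relations share planted nonnegative low-rank factors, plus
correlated expression profiles and a small rooted disease DAG, so the whole
pipeline can be exercised and its signal recovery measured without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hetnet import HeteroNetwork
from .similarity import DiseaseDAG, ExpressionProfiles


def figure3_toy() -> HeteroNetwork:
    """The PathSim/HeteSim worked-example network (no miRNAs).

    Adjacency rows: c1={d1}, c2={d1,d2}, c3={d2}, c4={d1,d2,d3}, c5={d3}.
    Under metapath CDC the instance counts satisfy M[c2,c4]=2, M[c2,c2]=2
    and M[c4,c4]=3, giving PathSim(c2,c4)=0.8 and HeteSim(c2,c4)=sqrt(6)/3.
    """
    A_CD = np.array([
        [1, 0, 0],  # c1
        [1, 1, 0],  # c2
        [0, 1, 0],  # c3
        [1, 1, 1],  # c4
        [0, 0, 1],  # c5
    ])
    return HeteroNetwork(
        circ_ids=[f"c{i}" for i in range(1, 6)],
        mirna_ids=[],
        disease_ids=[f"d{i}" for i in range(1, 4)],
        A_CD=A_CD,
        A_CM=np.zeros((5, 0), dtype=int),
        A_MD=np.zeros((0, 3), dtype=int),
    )


@dataclass
class SynthConfig:
    """Study conditions for the planted-structure generator."""

    m: int = 60            # circRNAs
    p: int = 30            # miRNAs
    n: int = 40            # diseases
    rank: int = 4          # planted latent dimension
    density_cd: float = 0.05
    density_cm: float = 0.10
    density_md: float = 0.10
    h: int = 10            # expression samples
    noise: float = 0.1     # expression noise sd
    signal: float = 4.0    # logit scale of the planted structure
    dag_cross_edges: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.m, self.p, self.n) < 2:
            raise ValueError("node counts must be >= 2")
        for d in (self.density_cd, self.density_cm, self.density_md):
            if not 0 < d < 1:
                raise ValueError("edge densities must lie in (0, 1)")
        if self.noise < 0:
            raise ValueError("noise must be nonnegative")


def _bernoulli_lowrank(U: np.ndarray, V: np.ndarray, density: float,
                       signal: float, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(logistic(signal * standardised(U V^T) + b)) with the
    intercept b calibrated by bisection to the target density."""
    S = U @ V.T
    S = (S - S.mean()) / max(S.std(), 1e-12)
    logits = signal * S

    def realised(b):
        return 1.0 / (1.0 + np.exp(-(logits + b)))

    lo, hi = -40.0, 40.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if realised(mid).mean() < density:
            lo = mid
        else:
            hi = mid
    prob = realised(0.5 * (lo + hi))
    if abs(prob.mean() - density) > 0.5 * density:
        raise ValueError(f"density target {density} unreachable")
    return (rng.random(prob.shape) < prob).astype(int)


def simulate_hetnet(cfg: SynthConfig | None = None) -> tuple[
        HeteroNetwork, ExpressionProfiles, DiseaseDAG, dict]:
    """Seeded planted-structure network + expression profiles + disease DAG.

    Returns ``(net, profiles, dag, truth)`` where ``truth`` holds the planted
    factors (U for circRNAs, V for diseases, Z for miRNAs) and the Bernoulli
    probabilities of the circRNA-disease relation.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    r = cfg.rank
    U = np.abs(rng.standard_normal((cfg.m, r)))
    V = np.abs(rng.standard_normal((cfg.n, r)))
    Z = np.abs(rng.standard_normal((cfg.p, r)))

    A_CD = _bernoulli_lowrank(U, V, cfg.density_cd, cfg.signal, rng)
    A_CM = _bernoulli_lowrank(U, Z, cfg.density_cm, cfg.signal, rng)
    A_MD = _bernoulli_lowrank(Z, V, cfg.density_md, cfg.signal, rng)

    net = HeteroNetwork(
        circ_ids=[f"circ{i:03d}" for i in range(cfg.m)],
        mirna_ids=[f"mir{i:03d}" for i in range(cfg.p)],
        disease_ids=[f"dis{i:03d}" for i in range(cfg.n)],
        A_CD=A_CD, A_CM=A_CM, A_MD=A_MD,
    )

    G = rng.standard_normal((r, cfg.h))
    expr = U @ G + cfg.noise * rng.standard_normal((cfg.m, cfg.h))
    profiles = ExpressionProfiles(circ_ids=list(net.circ_ids), matrix=expr)

    # rooted random tree over the diseases plus a few forward cross edges
    edges = [(net.disease_ids[i], net.disease_ids[int(rng.integers(i))])
             for i in range(1, cfg.n)]
    for _ in range(cfg.dag_cross_edges):
        child = int(rng.integers(1, cfg.n))
        parent = int(rng.integers(child))
        edge = (net.disease_ids[child], net.disease_ids[parent])
        if edge not in edges:
            edges.append(edge)
    dag = DiseaseDAG(parent_edges=edges)

    S = U @ V.T
    truth = {"U": U, "V": V, "Z": Z,
             "score_cd": (S - S.mean()) / max(S.std(), 1e-12)}
    return net, profiles, dag, truth
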