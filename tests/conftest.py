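import numpy as np
import pytest

from elcda import (HeteroNetwork, SynthConfig, build_dataset,
                   compute_similarity_bundle, figure3_toy, simulate_hetnet)


@pytest.fixture(scope="session")
def toy_net():
    return figure3_toy()


@pytest.fixture(scope="session")
def small_synth():
    """Small planted network for fast extractor/CV tests."""
    cfg = SynthConfig(m=16, p=8, n=12, rank=3, density_cd=0.15,
                      density_cm=0.2, density_md=0.2, seed=7)
    return simulate_hetnet(cfg)


@pytest.fixture(scope="session")
def small_bundle(small_synth):
    net, profiles, dag, _ = small_synth
    return compute_similarity_bundle(net, dag, profiles)


@pytest.fixture(scope="session")
def small_dataset(small_synth):
    net = small_synth[0]
    return build_dataset(net, seed=3)


def random_network(rng: np.random.Generator, m: int, p: int, n: int,
                   density: float = 0.4) -> HeteroNetwork:
    """Random dense-ish tri-partite network for oracle comparisons."""
    return HeteroNetwork(
        circ_ids=[f"c{i}" for i in range(m)],
        mirna_ids=[f"m{i}" for i in range(p)],
        disease_ids=[f"d{i}" for i in range(n)],
        A_CD=(rng.random((m, n)) < density).astype(int),
        A_CM=(rng.random((m, p)) < density).astype(int),
        A_MD=(rng.random((p, n)) < density).astype(int),
    )


def enumerate_walks(net: HeteroNetwork, type_sequence, start: int):
    """Brute-force enumeration of all walks following the type sequence."""
    walks = [[start]]
    for a, b in zip(type_sequence, type_sequence[1:]):
        A = net.adjacency(a, b)
        walks = [w + [j] for w in walks for j in np.nonzero(A[w[-1]])[0]]
    return [tuple(w) for w in walks]


def walk_count_matrix(net: HeteroNetwork, type_sequence) -> np.ndarray:
    sizes = {"C": net.n_circ, "M": net.n_mirna, "D": net.n_disease}
    rows, cols = sizes[type_sequence[0]], sizes[type_sequence[-1]]
    M = np.zeros((rows, cols), dtype=int)
    for x in range(rows):
        for walk in enumerate_walks(net, type_sequence, x):
            M[x, walk[-1]] += 1
    return M


def hetesim_recursive(net: HeteroNetwork, type_sequence, x: int, y: int) -> float:
    """Recursive relevance (averaging over out/in neighbours), normalised by
    the self-relevances so it matches the cosine simplification."""

    def rec(u, v, seq):
        if len(seq) == 1:
            return 1.0 if u == v else 0.0
        out = np.nonzero(net.adjacency(seq[0], seq[1])[u])[0]
        inc = np.nonzero(net.adjacency(seq[-1], seq[-2])[v])[0]
        if out.size == 0 or inc.size == 0:
            return 0.0
        total = sum(rec(o, i, seq[1:-1]) for o in out for i in inc)
        return total / (out.size * inc.size)

    num = rec(x, y, type_sequence)
    dx, dy = rec(x, x, type_sequence), rec(y, y, type_sequence)
    if dx <= 0 or dy <= 0:
        return 0.0
    return num / np.sqrt(dx * dy)
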