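"""Tri-partite heterogeneous network of circRNAs (C), miRNAs (M) and diseases (D).

The network holds three binary adjacency matrices — circRNA-disease,
circRNA-miRNA and miRNA-disease — and the metapath machinery shared by the
similarity measures and the feature extractors.  A metapath such as ``C-D-C``
defines a composite relation; the number of metapath *instances* (walks that
follow the type sequence) between two nodes is obtained by chaining the
adjacency matrices along the path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

NODE_TYPES = ("C", "M", "D")

#: Metapaths used for similarity integration, by anchor node type.
CIRC_METAPATHS = ("CDC", "CMC", "CDMDC", "CMDMC")
DISEASE_METAPATHS = ("DCD", "DMD", "DCMCD", "DMCMD")


@dataclass(frozen=True)
class Metapath:
    """An ordered sequence of node types with consecutive types distinct.

    ``Metapath.parse("CDC")`` builds the circRNA-disease-circRNA path used in
    the PathSim/HeteSim worked example.
    """

    type_sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        seq = self.type_sequence
        if len(seq) < 2:
            raise ValueError("a metapath needs at least two node types")
        for t in seq:
            if t not in NODE_TYPES:
                raise ValueError(f"unknown node type {t!r}; expected one of {NODE_TYPES}")
        for a, b in zip(seq, seq[1:]):
            if a == b:
                raise ValueError(f"consecutive node types must differ, got {a!r}{b!r}")

    @classmethod
    def parse(cls, spec: str) -> "Metapath":
        spec = spec.replace("-", "").strip().upper()
        return cls(tuple(spec))

    @property
    def edge_count(self) -> int:
        return len(self.type_sequence) - 1

    @property
    def is_palindromic(self) -> bool:
        return self.type_sequence == self.type_sequence[::-1]

    def __str__(self) -> str:
        return "".join(self.type_sequence)


@dataclass
class HeteroNetwork:
    """Node registries and binary adjacency matrices of the three relations."""

    circ_ids: list[str]
    mirna_ids: list[str]
    disease_ids: list[str]
    A_CD: np.ndarray  # m x n
    A_CM: np.ndarray  # m x p
    A_MD: np.ndarray  # p x n

    def __post_init__(self) -> None:
        m, p, n = len(self.circ_ids), len(self.mirna_ids), len(self.disease_ids)
        for name, ids in (("circ_ids", self.circ_ids), ("mirna_ids", self.mirna_ids),
                          ("disease_ids", self.disease_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"{name} contains duplicate identifiers")
        shapes = {"A_CD": (m, n), "A_CM": (m, p), "A_MD": (p, n)}
        for name, want in shapes.items():
            mat = np.asarray(getattr(self, name))
            if mat.shape != want:
                raise ValueError(f"{name} has shape {mat.shape}, expected {want}")
            if not np.isin(mat, (0, 1)).all():
                raise ValueError(f"{name} must be binary")
            setattr(self, name, mat.astype(np.int64))

    @property
    def n_circ(self) -> int:
        return len(self.circ_ids)

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    def adjacency(self, src: str, dst: str) -> np.ndarray:
        """Adjacency matrix for an ordered type pair, transposing as needed."""
        pair = (src, dst)
        table = {
            ("C", "D"): self.A_CD,
            ("D", "C"): self.A_CD.T,
            ("C", "M"): self.A_CM,
            ("M", "C"): self.A_CM.T,
            ("M", "D"): self.A_MD,
            ("D", "M"): self.A_MD.T,
        }
        if pair not in table:
            raise ValueError(f"no adjacency matrix for type pair {src}-{dst}")
        return table[pair]

    def ids_of(self, node_type: str) -> list[str]:
        return {"C": self.circ_ids, "M": self.mirna_ids, "D": self.disease_ids}[node_type]

    def with_cd(self, A_CD: np.ndarray) -> "HeteroNetwork":
        """Copy of the network with a replacement circRNA-disease matrix."""
        return HeteroNetwork(self.circ_ids, self.mirna_ids, self.disease_ids,
                             np.asarray(A_CD), self.A_CM, self.A_MD)


def build_network(
    edges_cd: Iterable[tuple[str, str]],
    edges_cm: Iterable[tuple[str, str]],
    edges_md: Iterable[tuple[str, str]],
) -> HeteroNetwork:
    """Materialise a :class:`HeteroNetwork` from three edge lists.

    Node order is first appearance in the inputs (circRNAs from the C-D list
    then the C-M list, and so on); duplicate edges collapse to a single 1.
    """
    edges_cd, edges_cm, edges_md = list(edges_cd), list(edges_cm), list(edges_md)
    for name, edges in (("circRNA-disease", edges_cd), ("circRNA-miRNA", edges_cm),
                        ("miRNA-disease", edges_md)):
        if not edges:
            raise ValueError(f"empty edge list for relation {name}")

    def register(ids: dict[str, int], key: str) -> int:
        if key not in ids:
            ids[key] = len(ids)
        return ids[key]

    circ: dict[str, int] = {}
    mirna: dict[str, int] = {}
    disease: dict[str, int] = {}
    for c, d in edges_cd:
        register(circ, c), register(disease, d)
    for c, mi in edges_cm:
        register(circ, c), register(mirna, mi)
    for mi, d in edges_md:
        register(mirna, mi), register(disease, d)

    A_CD = np.zeros((len(circ), len(disease)), dtype=np.int64)
    A_CM = np.zeros((len(circ), len(mirna)), dtype=np.int64)
    A_MD = np.zeros((len(mirna), len(disease)), dtype=np.int64)
    for c, d in edges_cd:
        A_CD[circ[c], disease[d]] = 1
    for c, mi in edges_cm:
        A_CM[circ[c], mirna[mi]] = 1
    for mi, d in edges_md:
        A_MD[mirna[mi], disease[d]] = 1
    return HeteroNetwork(list(circ), list(mirna), list(disease), A_CD, A_CM, A_MD)


def metapath_adjacency(net: HeteroNetwork, path: Metapath | str) -> np.ndarray:
    """Metapath instance counts: chained product of adjacency matrices.

    ``M[x, y]`` counts walks from ``x`` to ``y`` whose node types follow the
    path; walks may revisit nodes.
    """
    if isinstance(path, str):
        path = Metapath.parse(path)
    seq = path.type_sequence
    M = net.adjacency(seq[0], seq[1])
    for a, b in zip(seq[1:], seq[2:]):
        M = M @ net.adjacency(a, b)
    return M


def network_to_edge_lists(net: HeteroNetwork) -> dict[str, list[tuple[str, str]]]:
    """Inverse of :func:`build_network` (up to edge order)."""
    out: dict[str, list[tuple[str, str]]] = {}
    for key, mat, rows, cols in (
        ("cd", net.A_CD, net.circ_ids, net.disease_ids),
        ("cm", net.A_CM, net.circ_ids, net.mirna_ids),
        ("md", net.A_MD, net.mirna_ids, net.disease_ids),
    ):
        r, c = np.nonzero(mat)
        out[key] = [(rows[i], cols[j]) for i, j in zip(r, c)]
    return out
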