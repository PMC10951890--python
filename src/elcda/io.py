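"""Readers and writers for edge lists, matrices, profiles and reports.

Formats: two-column tab-separated edge lists (optional ``#`` header lines),
labelled dense CSV matrices (row index = identifiers), expression CSV with
an identifier column followed by sample columns, and JSON metric reports.
Every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hetnet import HeteroNetwork, build_network, network_to_edge_lists
from .similarity import DiseaseDAG, ExpressionProfiles


def read_edge_list(path) -> list[tuple[str, str]]:
    """Two-column TSV; lines starting with '#' are skipped."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated "
                                 f"columns, got {len(fields)}")
            pairs.append((fields[0], fields[1]))
    return pairs


def write_edge_list(path, pairs, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_matrix_csv(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate column identifiers")
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate row identifiers")
    return df


def write_matrix_csv(path, matrix, row_ids, col_ids) -> None:
    pd.DataFrame(np.asarray(matrix), index=row_ids, columns=col_ids).to_csv(path)


def read_dag_tsv(path, delta: float = 0.5) -> DiseaseDAG:
    return DiseaseDAG(parent_edges=read_edge_list(path), delta=delta)


def write_dag_tsv(path, dag: DiseaseDAG) -> None:
    write_edge_list(path, dag.parent_edges, header="child\tparent")


def read_expression_csv(path) -> ExpressionProfiles:
    df = read_matrix_csv(path)
    return ExpressionProfiles(circ_ids=list(df.index.astype(str)),
                              matrix=df.to_numpy(dtype=float))


def write_expression_csv(path, profiles: ExpressionProfiles) -> None:
    write_matrix_csv(path, profiles.matrix, profiles.circ_ids,
                     [f"s{i}" for i in range(profiles.matrix.shape[1])])


def read_network(cd_path, cm_path, md_path) -> HeteroNetwork:
    return build_network(read_edge_list(cd_path), read_edge_list(cm_path),
                         read_edge_list(md_path))


def write_network(outdir, net: HeteroNetwork) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lists = network_to_edge_lists(net)
    paths = {}
    for key, header in (("cd", "circRNA\tdisease"), ("cm", "circRNA\tmiRNA"),
                        ("md", "miRNA\tdisease")):
        p = outdir / f"edges_{key}.tsv"
        write_edge_list(p, lists[key], header=header)
        paths[key] = p
    return paths


def write_embeddings_csv(path, ids, matrix) -> None:
    write_matrix_csv(path, matrix, ids,
                     [f"e{i}" for i in range(np.asarray(matrix).shape[1])])


def write_metric_report(path, report) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def write_prediction_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def file_checksum(path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()
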