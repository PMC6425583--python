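"""Readers and writers for the package's on-disk formats.

Counts come in as MatrixMarket (.mtx plus barcode/gene text files) or as
dense CSV/TSV with a gene-id header row and cell ids in the first column.
Graphs go out as weighted edge lists (TSV) and GraphML; partitions,
layouts and pseudotime as small CSVs; abstraction results as GraphML,
adjacency CSV and a JSON summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .abstraction import AbstractionTree, PagaGraph
from .embedding import Layout
from .neighbors import NeighborGraph, graph_from_edges
from .partition import Partitioning
from .preprocess import CountMatrix
from .pseudotime import DptResult


# ---------------------------------------------------------------- counts

def read_counts_csv(path: str | Path, sep: str | None = None) -> CountMatrix:
    """Dense cells x genes table: header = gene ids, first column = cell ids."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.select_dtypes(exclude="number").shape[1]:
        raise ValueError(f"non-numeric entries in {path}")
    return CountMatrix(values=df.to_numpy(dtype=float), cell_ids=[str(i) for i in df.index], gene_ids=[str(c) for c in df.columns])


def write_counts_csv(counts: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(counts.values, index=counts.cell_ids, columns=counts.gene_ids).to_csv(path, float_format="%.10g")


def read_counts_mtx(mtx_path: str | Path, barcodes_path: str | Path, genes_path: str | Path) -> CountMatrix:
    """MatrixMarket matrix with one-id-per-line barcode and gene files.

    Accepts either cells x genes or the CellRanger genes x cells
    orientation (decided by matching the barcode file length).
    """
    m = scipy.io.mmread(str(mtx_path))
    m = np.asarray(m.todense()) if sp.issparse(m) else np.asarray(m)
    cells = [line.split("\t")[0].strip() for line in Path(barcodes_path).read_text().splitlines() if line.strip()]
    genes = [line.split("\t")[0].strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
    if m.shape[0] != len(cells) and m.shape[1] == len(cells):
        m = m.T
    return CountMatrix(values=m.astype(float), cell_ids=cells, gene_ids=genes)


def write_counts_mtx(counts: CountMatrix, mtx_path: str | Path, barcodes_path: str | Path, genes_path: str | Path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(counts.values))
    Path(barcodes_path).write_text("\n".join(counts.cell_ids) + "\n")
    Path(genes_path).write_text("\n".join(counts.gene_ids) + "\n")


# ----------------------------------------------------------------- graph

def write_graph_edges(graph: NeighborGraph, path: str | Path) -> None:
    """Weighted edge list TSV (u, v, weight) with 0-based cell indices, u < v."""
    edges = graph.edge_array()
    with open(path, "w") as fh:
        fh.write("# n_cells=%d k=%d kernel=%s\n" % (graph.n_cells, graph.k, graph.kernel))
        fh.write("u\tv\tweight\n")
        for u, v, w in edges:
            fh.write("%d\t%d\t%.12g\n" % (int(u), int(v), w))


def read_graph_edges(path: str | Path) -> NeighborGraph:
    meta = {"n_cells": 0, "k": 1, "kernel": "unit"}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            key, _, val = tok.partition("=")
            if key in meta:
                meta[key] = int(val) if key != "kernel" else val
    df = pd.read_csv(path, sep="\t", comment="#")
    n = int(meta["n_cells"]) or int(df[["u", "v"]].to_numpy().max()) + 1
    return graph_from_edges(df.to_numpy(), n_cells=n, k=int(meta["k"]), kernel=str(meta["kernel"]))


def write_graph_graphml(graph: NeighborGraph, path: str | Path) -> None:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_cells))
    for u, v, w in graph.edge_array():
        g.add_edge(int(u), int(v), weight=float(w))
    nx.write_graphml(g, str(path))


def read_velocity_edges(path: str | Path) -> np.ndarray:
    """Directed edge-list TSV (source_cell, target_cell, weight)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    arr = df.to_numpy(dtype=float)
    if arr.shape[1] == 2:
        arr = np.column_stack([arr, np.ones(len(arr))])
    return arr


def write_velocity_edges(arrows: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source_cell\ttarget_cell\tweight\n")
        for s, t, w in arrows:
            fh.write("%d\t%d\t%.12g\n" % (int(s), int(t), w))


# ------------------------------------------------------------- partition

def write_partition_csv(part: Partitioning, path: str | Path, cell_ids: list[str] | None = None) -> None:
    ids = cell_ids or [str(i) for i in range(part.n_cells)]
    pd.DataFrame({"cell_id": ids, "group_label": [part.name_of(g) for g in part.labels]}).to_csv(path, index=False)


def read_partition_csv(path: str | Path) -> dict:
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ----------------------------------------------------------- abstraction

def write_paga_graphml(paga: PagaGraph, path: str | Path, tree: AbstractionTree | None = None) -> None:
    g = nx.Graph()
    tree_edges = set(map(tuple, tree.edges)) if tree else set()
    for i in range(paga.n_groups):
        g.add_node(i, label=paga.group_names[i] if paga.group_names else str(i), size=int(paga.group_sizes[i]))
    for i, j in paga.edges_kept:
        attrs = {
            "theta": float(paga.theta[i, j]),
            "expected": float(paga.expected[i, j]),
            "inter_edges": float(paga.inter_edges[i, j]),
            "in_tree": (i, j) in tree_edges,
        }
        if paga.directed_tendency is not None:
            attrs["tendency"] = float(paga.directed_tendency[i, j])
        g.add_edge(i, j, **attrs)
    nx.write_graphml(g, str(path))


def write_paga_adjacency_csv(paga: PagaGraph, path: str | Path) -> None:
    names = paga.group_names or [str(i) for i in range(paga.n_groups)]
    pd.DataFrame(paga.theta, index=names, columns=names).to_csv(path, float_format="%.12g")


def paga_summary(paga: PagaGraph, tree: AbstractionTree | None = None) -> dict:
    s = {
        "n_groups": paga.n_groups,
        "threshold": paga.threshold,
        "n_edges_kept": len(paga.edges_kept),
        "edges": [
            {"i": i, "j": j, "theta": round(float(paga.theta[i, j]), 12)} for i, j in paga.edges_kept
        ],
        "group_sizes": [int(x) for x in paga.group_sizes],
    }
    if paga.directed_tendency is not None:
        for e in s["edges"]:
            e["tendency"] = round(float(paga.directed_tendency[e["i"], e["j"]]), 12)
    if tree is not None:
        s["tree_edges"] = [list(e) for e in tree.edges]
    return s


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------- layout

def write_layout_csv(layout: Layout, path: str | Path) -> None:
    ids = layout.ids or [str(i) for i in range(layout.n_nodes)]
    pd.DataFrame({"id": ids, "x": layout.positions[:, 0], "y": layout.positions[:, 1]}).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_layout_csv(path: str | Path, level: str = "cell") -> Layout:
    df = pd.read_csv(path)
    return Layout(positions=df[["x", "y"]].to_numpy(float), level=level, ids=[str(i) for i in df["id"]])


# ------------------------------------------------------------ pseudotime

def write_dpt_csv(dpt: DptResult, path: str | Path, cell_ids: list[str] | None = None) -> None:
    """CSV (cell_id, component, d); unreachable cells write d as 'inf'."""
    n = len(dpt.d)
    ids = cell_ids or [str(i) for i in range(n)]
    with open(path, "w") as fh:
        fh.write("cell_id,component,d\n")
        for i in range(n):
            d = dpt.d[i]
            fh.write("%s,%d,%s\n" % (ids[i], dpt.component_labels[i], "inf" if np.isinf(d) else "%.12g" % d))
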