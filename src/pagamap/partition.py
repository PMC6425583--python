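"""Graph partitioning: Louvain community detection or external labels.

Groups are the nodes of the abstracted graph, so the module enforces the
premise that a group is a set of *connected* cells: communities that are
internally disconnected are split into their connected components.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .neighbors import NeighborGraph


@dataclass
class Partitioning:
    """Cell -> group labeling with dense ids 0..n_groups-1."""

    labels: np.ndarray
    resolution: float | None = None
    source: str = "louvain"
    group_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size == 0:
            raise ValueError("empty partitioning")
        present = np.unique(self.labels)
        if present[0] != 0 or present[-1] != len(present) - 1:
            raise ValueError("labels must be dense 0..G-1 with no empty group")

    @property
    def n_cells(self) -> int:
        return self.labels.size

    @property
    def n_groups(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_groups)

    def indicator(self) -> sp.csr_matrix:
        """Sparse cells x groups membership indicator."""
        n = self.n_cells
        return sp.csr_matrix((np.ones(n), (np.arange(n), self.labels)), shape=(n, self.n_groups))

    def name_of(self, group: int) -> str:
        return self.group_names[group] if self.group_names else str(group)


def _relabel_dense(labels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Re-encode arbitrary labels to dense ids by first appearance."""
    seen: dict = {}
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out, [str(lab) for lab in seen]


def split_disconnected_groups(graph: NeighborGraph, labels: np.ndarray) -> np.ndarray:
    """Split groups whose induced subgraph is disconnected into components.

    New groups keep first-appearance order, so connected partitions pass
    through unchanged.
    """
    labels = np.asarray(labels)
    out = labels.astype(object).copy()
    for g in np.unique(labels):
        members = np.flatnonzero(labels == g)
        sub = graph.weights[members][:, members]
        n_comp, comp = connected_components(sub, directed=False)
        if n_comp > 1:
            for local, cell in enumerate(members):
                out[cell] = (g, comp[local])
    dense, _ = _relabel_dense(out)
    return dense


def partition_graph(
    graph: NeighborGraph,
    resolution: float = 1.0,
    seed: int = 0,
    use_weights: bool = True,
) -> Partitioning:
    """Louvain (multilevel modularity) communities at a given resolution.

    Deterministic for a fixed seed; internally disconnected communities
    are split so every group induces a connected subgraph.
    """
    if graph.n_cells == 0:
        raise ValueError("empty graph")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    coo = sp.triu(graph.weights, k=1).tocoo()
    g = ig.Graph(n=graph.n_cells, edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    weights = coo.data.tolist() if use_weights else None
    state = random.getstate()
    try:
        random.seed(seed)
        clustering = g.community_multilevel(weights=weights, resolution=resolution)
    finally:
        random.setstate(state)
    labels = np.asarray(clustering.membership, dtype=np.int64)
    labels = split_disconnected_groups(graph, labels)
    labels, _ = _relabel_dense(labels)
    return Partitioning(labels=labels, resolution=resolution, source="louvain")


def load_partition(table: dict, graph: NeighborGraph) -> Partitioning:
    """Ingest an external cell -> label mapping for the cells of a graph.

    ``table`` maps cell ids (or integer cell indices when the graph has no
    ids) to arbitrary hashable labels.  Labels are re-encoded to dense ids
    in first-appearance order over the graph's cell order.
    """
    ids = [str(c) for c in (graph.cell_ids if graph.cell_ids is not None else range(graph.n_cells))]
    table = {str(key): val for key, val in table.items()}
    missing = [c for c in ids if c not in table]
    if missing:
        raise KeyError(f"partition table missing {len(missing)} cells: {missing[:10]}")
    unknown = [k for k in table if k not in set(ids)]
    if unknown:
        warnings.warn(f"partition table has {len(unknown)} unknown cells; ignored", stacklevel=2)
    raw = np.array([table[c] for c in ids], dtype=object)
    labels, names = _relabel_dense(raw)
    return Partitioning(labels=labels, resolution=None, source="external", group_names=names)
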