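"""Partition-based graph abstraction: the connectivity test statistic.

Given a neighborhood graph and a partitioning into groups, the abstracted
graph G* has one node per group and edge weights

    theta_ij = min(1, e_ij / e^_ij)

where e_ij is the observed number (or weight) of inter-edges between
groups i and j and e^_ij the count expected under random assignment of
edges.  theta reads as a confidence that two groups are truly connected;
thresholding it removes spurious edges, and a minimum spanning tree under
inverse connectivity extracts a lineage-tree skeleton.

Null models (pluggable, ``null=`` argument):

``knn`` (default)
    e^_ij = k * n_i * n_j / (n_c - 1): each of the k * n_i edge stubs of
    group i lands on a given other node with probability 1/(n_c - 1),
    where n_c counts the cells of the connected component(s) containing
    the pair.  Conditioning on the component makes theta independent of
    unrelated disconnected parts of the data, so adding a detached cluster
    leaves every other entry bit-identical.
``knn_global``
    same formula with n_c replaced by the total cell count n.
``degrees``
    e^_ij = (d_i * n_j + d_j * n_i) / (2 * (n - 1)) with d_i the summed
    degree of group i; conditions on realized degrees instead of k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .neighbors import NeighborGraph
from .partition import Partitioning


@dataclass
class InterEdgeCounts:
    """Summed inter-edge counts (or weights) between all group pairs."""

    e: np.ndarray  # G x G symmetric, zero diagonal
    e_total: float  # total undirected edge count/weight in the graph
    per_group_degree: np.ndarray  # d_i: summed edge endpoints in group i
    group_sizes: np.ndarray
    n_cells: int
    group_comp: np.ndarray  # G x C boolean: group has cells in component
    comp_sizes: np.ndarray  # cells per connected component
    weighted: bool = False


@dataclass
class PagaGraph:
    """Abstracted graph G*: per-pair connectivity over the groups."""

    theta: np.ndarray  # G x G symmetric in [0, 1], zero diagonal
    expected: np.ndarray  # null inter-edge counts e^_ij
    inter_edges: np.ndarray  # observed e_ij
    group_sizes: np.ndarray
    threshold: float = 0.0
    edges_kept: list = field(default_factory=list)  # (i, j) with i < j
    directed_tendency: np.ndarray | None = None  # antisymmetric in [-1, 1]
    group_names: list[str] | None = None

    @property
    def n_groups(self) -> int:
        return self.theta.shape[0]

    def validate(self) -> None:
        t = self.theta
        if not np.allclose(t, t.T):
            raise ValueError("theta must be symmetric")
        if np.any(np.diag(t) != 0):
            raise ValueError("theta must have zero diagonal")
        if t.min() < 0 or t.max() > 1:
            raise ValueError("theta must lie in [0, 1]")
        if self.directed_tendency is not None:
            d = self.directed_tendency
            if not np.allclose(d, -d.T):
                raise ValueError("directed_tendency must be antisymmetric")

    def kept_adjacency(self) -> np.ndarray:
        """theta restricted to the kept edge set (dense G x G)."""
        a = np.zeros_like(self.theta)
        for i, j in self.edges_kept:
            a[i, j] = a[j, i] = self.theta[i, j]
        return a

    def oriented_edges(self) -> list[tuple[int, int, float]]:
        """Kept edges oriented by the sign of the transition tendency.

        Returns (source, target, |tendency|) triples; edges with zero
        tendency keep the (i, j) order with confidence 0.
        """
        if self.directed_tendency is None:
            raise ValueError("no directed tendency attached")
        out = []
        for i, j in self.edges_kept:
            t = self.directed_tendency[i, j]
            if t >= 0:
                out.append((i, j, float(abs(t))))
            else:
                out.append((j, i, float(abs(t))))
        return out


@dataclass
class AbstractionTree:
    """Spanning forest of G* under inverse-connectivity edge weights."""

    edges: list  # (i, j) pairs with i < j
    n_groups: int
    weight_used: str = "inverse connectivity"


def count_inter_edges(
    graph: NeighborGraph, part: Partitioning, use_weights: bool = False
) -> InterEdgeCounts:
    """Count edges (or sum weights) between every pair of groups.

    Each undirected edge with endpoints in groups i != j contributes once
    to e_ij (and, by symmetry of the returned matrix, once to e_ji).
    """
    if part.n_cells != graph.n_cells:
        raise ValueError("partitioning does not cover the graph")
    a = graph.weights.copy()
    if not use_weights:
        a.data = np.ones_like(a.data)
    b = part.indicator()
    m = np.asarray((b.T @ a @ b).todense())
    e = m.copy()
    np.fill_diagonal(e, 0.0)
    n_comp, comp = graph.components()
    comp_sizes = np.bincount(comp, minlength=n_comp)
    group_comp = np.zeros((part.n_groups, n_comp), dtype=bool)
    group_comp[part.labels, comp] = True
    return InterEdgeCounts(
        e=e,
        e_total=float(a.sum() / 2.0),
        per_group_degree=m.sum(axis=1),
        group_sizes=part.sizes,
        n_cells=graph.n_cells,
        group_comp=group_comp,
        comp_sizes=comp_sizes,
        weighted=use_weights,
    )


def _pair_component_cells(counts: InterEdgeCounts, i: int, j: int) -> float:
    mask = counts.group_comp[i] | counts.group_comp[j]
    return float(counts.comp_sizes[mask].sum())


def expected_null(counts: InterEdgeCounts, k: int, null: str = "knn") -> np.ndarray:
    """Expected inter-edge counts e^_ij under the chosen null model."""
    g = len(counts.group_sizes)
    ns = counts.group_sizes.astype(float)
    d = counts.per_group_degree
    ehat = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            if null == "knn":
                nc = _pair_component_cells(counts, i, j)
                denom = nc - 1.0
                val = k * ns[i] * ns[j] / denom if denom > 0 else 0.0
            elif null == "knn_global":
                denom = counts.n_cells - 1.0
                val = k * ns[i] * ns[j] / denom if denom > 0 else 0.0
            elif null == "degrees":
                denom = 2.0 * (counts.n_cells - 1.0)
                val = (d[i] * ns[j] + d[j] * ns[i]) / denom if denom > 0 else 0.0
            else:
                raise ValueError(f"unknown null model {null!r}")
            ehat[i, j] = ehat[j, i] = val
    return ehat


def connectivity_undirected(
    counts: InterEdgeCounts,
    part: Partitioning,
    k: int,
    null="knn",
) -> PagaGraph:
    """The PAGA connectivity statistic theta_ij = min(1, e_ij / e^_ij).

    ``null`` is a name from :func:`expected_null` or a callable
    ``(counts, part, k) -> e^`` returning a G x G matrix.
    """
    e = counts.e
    ehat = null(counts, part, k) if callable(null) else expected_null(counts, k, null)
    g = e.shape[0]
    theta = np.zeros((g, g))
    degenerate = False
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(g):
            for j in range(i + 1, g):
                if e[i, j] == 0:
                    continue
                if ehat[i, j] == 0:
                    theta[i, j] = theta[j, i] = 1.0
                    degenerate = True
                else:
                    theta[i, j] = theta[j, i] = min(1.0, e[i, j] / ehat[i, j])
    if degenerate:
        warnings.warn("degenerate null (e^=0 with observed inter-edges); theta set to 1", stacklevel=2)
    edges = [(i, j) for i in range(g) for j in range(i + 1, g) if e[i, j] > 0]
    return PagaGraph(
        theta=theta,
        expected=ehat,
        inter_edges=e.copy(),
        group_sizes=counts.group_sizes.copy(),
        threshold=0.0,
        edges_kept=edges,
        group_names=part.group_names,
    )


def connectivity_directed(
    velocity_edges,
    part: Partitioning,
    base: PagaGraph | None = None,
    use_weights: bool = True,
) -> PagaGraph:
    """Transition tendency between groups from a directed velocity graph.

    With f_ij the summed arrows from group i to group j, the tendency is
    t_ij = (f_ij - f_ji) / (f_ij + f_ji) (0 when no arrows connect the
    pair): +1 means all arrows point i -> j.  When ``base`` is given, its
    undirected connectivity and kept edges are carried over so the
    tendency orients them; otherwise a tendency-only graph is returned.
    """
    rows = list(velocity_edges)
    arr = np.asarray(rows, dtype=float).reshape(-1, 3) if rows else np.empty((0, 3))
    g = part.n_groups
    f = np.zeros((g, g))
    if arr.size == 0:
        warnings.warn("empty velocity graph; tendency is all zero", stacklevel=2)
    else:
        src = part.labels[arr[:, 0].astype(int)]
        dst = part.labels[arr[:, 1].astype(int)]
        w = arr[:, 2] if use_weights else np.ones(len(arr))
        np.add.at(f, (src, dst), w)
    np.fill_diagonal(f, 0.0)
    tot = f + f.T
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(tot > 0, (f - f.T) / np.where(tot > 0, tot, 1.0), 0.0)
    if base is not None:
        return PagaGraph(
            theta=base.theta.copy(),
            expected=base.expected.copy(),
            inter_edges=base.inter_edges.copy(),
            group_sizes=base.group_sizes.copy(),
            threshold=base.threshold,
            edges_kept=list(base.edges_kept),
            directed_tendency=t,
            group_names=base.group_names,
        )
    sym = f + f.T
    np.fill_diagonal(sym, 0.0)
    return PagaGraph(
        theta=np.zeros((g, g)),
        expected=np.zeros((g, g)),
        inter_edges=sym,
        group_sizes=part.sizes,
        threshold=0.0,
        edges_kept=[],
        directed_tendency=t,
        group_names=part.group_names,
    )


def threshold_graph(paga: PagaGraph, threshold: float = 0.01) -> PagaGraph:
    """Keep only edges with theta >= threshold (and observed inter-edges)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    g = paga.n_groups
    kept = [
        (i, j)
        for i in range(g)
        for j in range(i + 1, g)
        if paga.inter_edges[i, j] > 0 and paga.theta[i, j] >= threshold
    ]
    return PagaGraph(
        theta=paga.theta.copy(),
        expected=paga.expected.copy(),
        inter_edges=paga.inter_edges.copy(),
        group_sizes=paga.group_sizes.copy(),
        threshold=threshold,
        edges_kept=kept,
        directed_tendency=None if paga.directed_tendency is None else paga.directed_tendency.copy(),
        group_names=paga.group_names,
    )


def spanning_tree(paga: PagaGraph) -> AbstractionTree:
    """Minimum spanning forest of the kept edges under weight 1/theta.

    Kruskal with ties broken by lexicographic (i, j); one tree per
    connected component of the thresholded graph (isolated groups are
    singleton trees).
    """
    g = paga.n_groups
    if g < 1:
        raise ValueError("empty abstraction")
    edges = sorted(
        ((1.0 / max(paga.theta[i, j], 1e-300), i, j) for i, j in paga.edges_kept),
    )
    parent = list(range(g))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = []
    for _, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((i, j))
    return AbstractionTree(edges=tree, n_groups=g)


def overlap_fractions(fine: Partitioning, coarse: Partitioning) -> np.ndarray:
    """Row-normalized contingency: fraction of each fine group's cells per
    coarse group (shape fine.n_groups x coarse.n_groups, rows sum to 1)."""
    if fine.n_cells != coarse.n_cells:
        raise ValueError("partitions cover different cell sets")
    contingency = np.asarray((fine.indicator().T @ coarse.indicator()).todense())
    return contingency / contingency.sum(axis=1, keepdims=True)


def map_resolutions(fine: Partitioning, coarse: Partitioning) -> dict[int, tuple[int, float]]:
    """Associate each fine group with the coarse group holding most of it.

    Returns {fine_group: (coarse_group, overlap_fraction)}; ties resolve
    to the lower coarse id.
    """
    frac = overlap_fractions(fine, coarse)
    out: dict[int, tuple[int, float]] = {}
    for i in range(fine.n_groups):
        j = int(np.argmax(frac[i]))
        out[i] = (j, float(frac[i, j]))
    return out
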