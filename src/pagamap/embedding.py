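"""Coarse-graph layouts and topology-preserving single-cell embeddings.

The coarse PAGA graph is laid out with a force-directed iteration; single
cells are then seeded inside non-overlapping rectangles around their
group's coarse position (edge length = half the distance to the nearest
coarse neighbor), which preserves the abstracted topology in the initial
state, and optionally refined on the single-cell graph.  The reverse map
places coarse nodes on the coordinate-wise median of their members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .abstraction import PagaGraph
from .neighbors import NeighborGraph
from .partition import Partitioning


@dataclass
class Layout:
    """2-D positions for nodes at group or cell level."""

    positions: np.ndarray  # (n, 2)
    level: str = "cell"  # "group" | "cell"
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]


def _fruchterman_reingold(
    adj: sp.csr_matrix,
    pos: np.ndarray,
    n_iter: int,
    seed: int,
    repulsion_power: int = 1,
) -> np.ndarray:
    """Deterministic Fruchterman-Reingold iteration (dense repulsion).

    Attraction along edges scales with the edge weight; repulsion is
    k^2/d (classic FR) or k^2/d^2 for a sharper, UMAP-like profile
    (``repulsion_power=2``).  Temperature decays linearly.
    """
    n = pos.shape[0]
    if n_iter <= 0 or n == 1:
        return pos.copy()
    pos = pos.copy()
    span = pos.max(axis=0) - pos.min(axis=0)
    scale = max(float(span.max()), 1.0)
    k_opt = scale / np.sqrt(n)
    coo = sp.triu(adj, k=1).tocoo()
    eu, ev, ew = coo.row, coo.col, coo.data
    t0 = 0.1 * scale
    for it in range(n_iter):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((delta**2).sum(axis=2))
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, 1e-9)
        rep = k_opt**2 / dist**repulsion_power
        np.fill_diagonal(rep, 0.0)
        disp = (delta / dist[:, :, None] * rep[:, :, None]).sum(axis=1)
        if len(eu):
            dvec = pos[eu] - pos[ev]
            edist = np.maximum(np.sqrt((dvec**2).sum(axis=1)), 1e-9)
            f = (edist / k_opt) * ew  # attraction magnitude per unit vector
            pull = dvec / edist[:, None] * f[:, None]
            np.add.at(disp, eu, -pull)
            np.add.at(disp, ev, pull)
        length = np.maximum(np.sqrt((disp**2).sum(axis=1)), 1e-12)
        temp = t0 * (1.0 - it / n_iter)
        pos += disp / length[:, None] * np.minimum(length, temp)[:, None]
    return pos


def layout_paga_graph(paga: PagaGraph, seed: int = 0, n_iter: int = 200) -> Layout:
    """Force-directed 2-D layout of the thresholded abstracted graph.

    Edge attraction is proportional to theta.  Connected components are
    laid out independently and tiled on a grid so they never overlap.
    """
    g = paga.n_groups
    rng = np.random.default_rng(seed)
    adj = sp.csr_matrix((g, g))
    if paga.edges_kept:
        i, j = np.array(paga.edges_kept).T
        w = paga.theta[i, j]
        adj = sp.csr_matrix((w, (i, j)), shape=(g, g))
        adj = adj + adj.T
    n_comp, comp = connected_components(adj, directed=False)
    pos = np.zeros((g, 2))
    extents = []
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        p = rng.uniform(-1, 1, size=(len(members), 2))
        sub = adj[members][:, members].tocsr()
        p = _fruchterman_reingold(sub, p, n_iter=n_iter, seed=seed)
        p -= p.mean(axis=0)
        pos[members] = p
        extents.append(max(float(np.abs(p).max()), 0.5) if len(members) > 1 else 0.5)
    if n_comp > 1:
        # tile components on a grid, spaced by the largest extent
        pitch = 3.0 * max(extents)
        side = int(np.ceil(np.sqrt(n_comp)))
        for c in range(n_comp):
            members = np.flatnonzero(comp == c)
            pos[members] += pitch * np.array([c % side, c // side])
    return Layout(positions=pos, level="group", ids=paga.group_names)


def rectangle_half_edges(coarse_positions: np.ndarray) -> np.ndarray:
    """Rectangle half-edge per coarse node: a quarter of the Euclidean
    distance to its nearest coarse neighbor.

    The square's full edge length is then half that distance, which
    guarantees disjoint axis-aligned rectangles for any configuration:
    two squares overlap only if the Chebyshev distance of their centers
    is below the sum of half-edges, and ||c_u - c_v||_inf >=
    ||c_u - c_v||_2 / sqrt(2) > (h_u + h_v).
    """
    n = coarse_positions.shape[0]
    if n == 1:
        warnings.warn("single coarse node; rectangle half-edge defaults to 1.0", stacklevel=2)
        return np.array([1.0])
    d = np.sqrt(((coarse_positions[:, None, :] - coarse_positions[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    return 0.25 * d.min(axis=1)


def init_fine_from_coarse(coarse_layout: Layout, association, seed: int = 0) -> Layout:
    """Seed fine nodes uniformly inside rectangles around coarse nodes.

    ``association`` maps each fine node index to a coarse node index (an
    array-like, e.g. a Partitioning's labels for cell-level init, or a
    {fine_group: coarse_group} dict for group-level init).  Rectangles are
    axis-aligned squares whose edge length is half the distance to the
    nearest coarse neighbor (see :func:`rectangle_half_edges`), hence
    mutually disjoint.
    """
    if isinstance(association, dict):
        assoc = np.array([association[i][0] if isinstance(association[i], tuple) else association[i] for i in range(len(association))])
    else:
        assoc = np.asarray(association, dtype=int)
    cpos = coarse_layout.positions
    if assoc.min() < 0 or assoc.max() >= cpos.shape[0]:
        raise ValueError("association refers to coarse nodes without positions")
    half = rectangle_half_edges(cpos)
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(-1.0, 1.0, size=(len(assoc), 2))
    pos = cpos[assoc] + offsets * half[assoc][:, None]
    return Layout(positions=pos, level="cell")


def coarse_from_fine(fine_layout: Layout, part: Partitioning) -> Layout:
    """Coarse positions as the coordinate-wise median of group members."""
    if fine_layout.n_nodes != part.n_cells:
        raise ValueError("fine layout does not cover the partitioning")
    pos = np.zeros((part.n_groups, 2))
    for g in range(part.n_groups):
        pos[g] = np.median(fine_layout.positions[part.labels == g], axis=0)
    return Layout(positions=pos, level="group", ids=part.group_names)


def embed_cells(
    graph: NeighborGraph,
    init: Layout,
    method: str = "force_directed",
    n_iter: int = 50,
    seed: int = 0,
) -> Layout:
    """Refine a single-cell layout from an initialization.

    ``force_directed`` runs the package's Fruchterman-Reingold engine on
    the weighted cell graph; ``umap_like`` uses the same engine with a
    sharper 1/d^2 repulsion profile.  ``n_iter=0`` returns the
    initialization unchanged.  External engines (ForceAtlas2, UMAP) can be
    plugged in by passing their output through :class:`Layout`.
    """
    if init.n_nodes != graph.n_cells:
        raise ValueError("init layout does not cover the graph")
    if method not in ("force_directed", "umap_like"):
        raise ValueError("method must be 'force_directed' or 'umap_like'")
    if n_iter == 0:
        return Layout(positions=init.positions.copy(), level="cell", ids=init.ids)
    power = 1 if method == "force_directed" else 2
    pos = _fruchterman_reingold(graph.weights, init.positions, n_iter=n_iter, seed=seed, repulsion_power=power)
    return Layout(positions=pos, level="cell", ids=init.ids)
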