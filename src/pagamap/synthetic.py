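"""Ground-truth simulator: branching expression manifolds with noise.

The generator emulates tree-structured differentiation: each segment of a
given segment-level topology is a straight line in gene space (random
direction, unit length, continuous at branch points), cells are sampled
along segments (uniformly by default, or with a Beta density to emulate
variable sampling), and isotropic Gaussian noise is added.  Optional
extras append a far-offset disconnected cluster and directed cell-level
arrows that emulate an RNA-velocity transition graph.

Every dataset records its full ground truth (segment topology, per-cell
segment and normalized time, arrows, parameters, seed), which drives all
recovery tests in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .neighbors import exact_knn


@dataclass
class SimulatedDataset:
    """Expression matrix plus complete generator ground truth."""

    expr: np.ndarray  # cells x genes
    cell_ids: list[str]
    gene_ids: list[str]
    true_topology: nx.Graph  # nodes = segment ids
    true_branch: np.ndarray  # cell -> segment id
    true_time: np.ndarray  # cell -> [0, 1]
    true_arrows: np.ndarray | None  # (source, target, weight) rows
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    def diameter(self) -> float:
        """Extent of the expression manifold (max norm from centroid, x2)."""
        c = self.expr.mean(axis=0)
        return 2.0 * float(np.sqrt(((self.expr - c) ** 2).sum(axis=1)).max())


def linear_topology(n_segments: int = 1) -> nx.Graph:
    """Chain of segments 0-1-...-(n-1)."""
    g = nx.Graph()
    g.add_nodes_from(range(n_segments))
    g.add_edges_from((i, i + 1) for i in range(n_segments - 1))
    return g


def y_topology() -> nx.Graph:
    """One branch point: segment 0 splits into segments 1 and 2."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (0, 2)])
    return g


def double_branch_topology() -> nx.Graph:
    """Two successive branch points: 0 -> (1, 2), 1 -> (3, 4)."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (0, 2), (1, 3), (1, 4)])
    return g


def _segment_layout(topology: nx.Graph, rng: np.random.Generator, n_genes: int):
    """Start point, unit direction and depth for each segment.

    Segments are rooted per connected component at the lowest node id;
    each child segment starts where its parent ends, giving a continuous
    piecewise-linear tree in gene space.  Disconnected components are
    offset along fresh random directions so they do not intersect.
    """
    start: dict = {}
    direction: dict = {}
    depth: dict = {}
    comp_offset = np.zeros(n_genes)
    for comp in sorted(nx.connected_components(topology), key=min):
        root = min(comp)
        order = list(nx.bfs_tree(topology.subgraph(comp), root))
        for node in order:
            direction[node] = _unit(rng.normal(size=n_genes))
        start[root] = comp_offset.copy()
        depth[root] = 0
        for node in order:
            for child in sorted(topology.neighbors(node)):
                if child not in start:
                    start[child] = start[node] + direction[node]
                    depth[child] = depth[node] + 1
        comp_offset = comp_offset + 4.0 * _unit(rng.normal(size=n_genes))
    return start, direction, depth


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def simulate_tree(
    topology: nx.Graph | list | None = None,
    cells_per_segment: int = 200,
    n_genes: int = 50,
    noise_sd: float = 0.3,
    seed: int = 0,
    density: tuple[float, float] | None = None,
    emission: str = "linear",
) -> SimulatedDataset:
    """Sample cells along a piecewise-linear segment tree in gene space.

    Parameters
    ----------
    topology
        Segment-level graph (nodes = segment ids) or an edge list; default
        is a single segment.  Forests are allowed and produce disconnected
        manifolds.
    cells_per_segment
        Cells sampled on each segment (int, or {segment: int} dict).
    noise_sd
        Magnitude of the isotropic noise displacement relative to the
        (unit) segment length: the expected norm of a cell's noise vector
        is ~noise_sd, i.e. per-gene sd = noise_sd / sqrt(n_genes).  (A
        per-gene sd of 0.3 in 50 dimensions would displace cells by twice
        the segment length and destroy the manifold.)
    density
        Optional (a, b) parameters of a Beta distribution for the
        position along each segment; None = uniform.
    emission
        ``linear`` emits the noisy coordinates directly (post-
        preprocessing scale); ``poisson`` emits Poisson counts with rates
        affine in the coordinates, for exercising count preprocessing.
    """
    if topology is None:
        topology = linear_topology(1)
    elif not isinstance(topology, nx.Graph):
        g = nx.Graph()
        g.add_edges_from(topology)
        topology = g
    if topology.number_of_nodes() == 0:
        raise ValueError("topology must have at least one segment")
    rng = np.random.default_rng(seed)
    start, direction, depth = _segment_layout(topology, rng, n_genes)
    max_depth = max(depth.values()) + 1

    xs, branch, time = [], [], []
    segments = sorted(topology.nodes())
    for seg in segments:
        m = cells_per_segment[seg] if isinstance(cells_per_segment, dict) else cells_per_segment
        t = rng.beta(*density, size=m) if density else rng.uniform(size=m)
        pos = start[seg][None, :] + t[:, None] * direction[seg][None, :]
        xs.append(pos)
        branch.extend([seg] * m)
        time.extend(((depth[seg] + t) / max_depth).tolist())
    x = np.vstack(xs)
    if noise_sd > 0:
        x = x + rng.normal(scale=noise_sd / np.sqrt(n_genes), size=x.shape)
    if emission == "poisson":
        lam = np.clip(x - x.min() + 0.1, 0.0, None)
        x = rng.poisson(lam).astype(float)
    elif emission != "linear":
        raise ValueError("emission must be 'linear' or 'poisson'")

    params = {
        "topology_edges": sorted(map(tuple, topology.edges())),
        "topology_nodes": segments,
        "cells_per_segment": cells_per_segment,
        "n_genes": n_genes,
        "noise_sd": noise_sd,
        "density": density,
        "emission": emission,
    }
    n = x.shape[0]
    return SimulatedDataset(
        expr=x,
        cell_ids=[f"cell{i}" for i in range(n)],
        gene_ids=[f"gene{j}" for j in range(n_genes)],
        true_topology=topology.copy(),
        true_branch=np.asarray(branch, dtype=np.int64),
        true_time=np.asarray(time, dtype=float),
        true_arrows=None,
        seed=seed,
        params=params,
    )


def add_disconnected_cluster(
    ds: SimulatedDataset,
    n_cells: int = 100,
    offset: float | None = None,
    sd: float | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Append an isotropic Gaussian blob far from the manifold.

    ``offset`` is the distance of the blob center from the data centroid;
    the default (10 x manifold diameter) guarantees that no kNN edge links
    the blob to the manifold for any reasonable k.  The original cells'
    expression is unchanged and the topology gains an isolated node.
    """
    rng = np.random.default_rng(seed)
    if offset is None:
        offset = 10.0 * ds.diameter()
    if sd is None:
        sd = float(ds.params.get("noise_sd", 0.3)) or 0.1
    center = ds.expr.mean(axis=0) + offset * _unit(rng.normal(size=ds.n_genes))
    blob = center[None, :] + rng.normal(scale=sd, size=(n_cells, ds.n_genes))
    new_seg = max(ds.true_topology.nodes()) + 1
    topo = ds.true_topology.copy()
    topo.add_node(new_seg)
    return SimulatedDataset(
        expr=np.vstack([ds.expr, blob]),
        cell_ids=ds.cell_ids + [f"blob{i}" for i in range(n_cells)],
        gene_ids=list(ds.gene_ids),
        true_topology=topo,
        true_branch=np.concatenate([ds.true_branch, np.full(n_cells, new_seg, dtype=np.int64)]),
        true_time=np.concatenate([ds.true_time, np.zeros(n_cells)]),
        true_arrows=None if ds.true_arrows is None else ds.true_arrows.copy(),
        seed=ds.seed,
        params={**ds.params, "blob": {"n_cells": n_cells, "offset": offset, "sd": sd, "seed": seed}},
    )


def simulate_arrows(ds: SimulatedDataset, k: int = 15, flip_rate: float = 0.0, seed: int = 0) -> SimulatedDataset:
    """Directed cell-level arrows emulating an RNA-velocity graph.

    Every union-symmetrized kNN edge becomes one arrow oriented from the
    cell with lower true time to the one with higher (ties to the lower
    index), then flipped independently with probability ``flip_rate``.
    """
    if not 0.0 <= flip_rate <= 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    idx, _ = exact_knn(ds.expr, k)
    pairs = set()
    for i in range(ds.n_cells):
        for j in idx[i]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    arrows = []
    for u, v in sorted(pairs):
        lo, hi = (u, v) if (ds.true_time[u], u) <= (ds.true_time[v], v) else (v, u)
        if rng.uniform() < flip_rate:
            lo, hi = hi, lo
        arrows.append((lo, hi, 1.0))
    return replace(
        ds,
        true_arrows=np.asarray(arrows, dtype=float),
        params={**ds.params, "arrows": {"k": k, "flip_rate": flip_rate, "seed": seed}},
    )
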