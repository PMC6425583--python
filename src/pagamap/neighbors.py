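"""Symmetrized kNN graph construction with kernel edge weights.

Each cell is connected to its k nearest neighbors (Euclidean distance in
the chosen representation); the directed relation is symmetrized by union,
keeping the larger weight when both directions exist.  Edge weights come
from one of three kernels:

``unit``
    every edge has weight 1 (pure topology).
``exponential``
    the smooth-kNN weighting of the UMAP family: per cell, weights
    exp(-(d - rho)/sigma) with rho the distance to the nearest neighbor
    (local connectivity 1) and sigma solved so the weights sum to log2(k).
``adaptive_gaussian``
    diffusion-map style kernel exp(-d^2 / (sigma_i * sigma_j)) with the
    per-cell bandwidth sigma_i set to the distance to the ceil(k/2)-th
    neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

KERNELS = ("exponential", "adaptive_gaussian", "unit")


@dataclass
class NeighborGraph:
    """Weighted symmetric neighborhood graph of single cells.

    ``weights`` is a symmetric CSR matrix with zero diagonal and entries in
    (0, 1]; ``distances`` holds the corresponding Euclidean distances (also
    symmetric; zero-distance duplicate points keep their edge in
    ``weights`` with weight 1).
    """

    weights: sp.csr_matrix
    distances: sp.csr_matrix
    k: int
    kernel: str = "exponential"
    metric_name: str = "euclidean"
    cell_ids: list[str] | None = None

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    def degrees(self) -> np.ndarray:
        """Number of neighbors of each cell in the symmetrized graph."""
        return np.diff(self.weights.indptr)

    def components(self) -> tuple[int, np.ndarray]:
        """Connected components (count, per-cell label)."""
        return connected_components(self.weights, directed=False)

    def edge_array(self) -> np.ndarray:
        """Edges as an array of (u, v, weight) rows with u < v."""
        coo = sp.triu(self.weights, k=1).tocoo()
        return np.column_stack([coo.row, coo.col, coo.data])

    def validate(self) -> None:
        w = self.weights
        if (w != w.T).nnz:
            raise ValueError("weights must be symmetric")
        if w.diagonal().any():
            raise ValueError("weights must have zero diagonal")
        if w.nnz and (w.data <= 0).any() or w.nnz and (w.data > 1 + 1e-12).any():
            raise ValueError("weights must lie in (0, 1]")


def exact_knn(coords: np.ndarray, k: int, block: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Exact k nearest neighbors with ties broken by lowest cell index.

    Returns (indices, distances), each of shape (n, k), excluding self.
    Uses blocked pairwise distances with a stable argsort, so identical
    distances always resolve to the smaller index.
    """
    n = coords.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells ({n})")
    idx = np.empty((n, k), dtype=np.int64)
    dist = np.empty((n, k), dtype=float)
    sq = (coords**2).sum(axis=1)
    for start in range(0, n, block):
        stop = min(start + block, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * coords[start:stop] @ coords.T
        np.maximum(d2, 0.0, out=d2)
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = np.inf  # exclude self
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        idx[start:stop] = order
        dist[start:stop] = np.sqrt(np.take_along_axis(d2, order, axis=1))
    return idx, dist


def _smooth_knn_weights(dist: np.ndarray, k: int, n_iter: int = 64) -> np.ndarray:
    """UMAP-family smooth kNN weights: exp(-(d-rho)/sigma), sum = log2(k)."""
    target = np.log2(k) if k > 1 else 1.0
    rho = dist[:, 0]
    shifted = np.maximum(dist - rho[:, None], 0.0)
    lo = np.full(dist.shape[0], 1e-12)
    hi = np.full(dist.shape[0], 1.0)
    # grow hi until the weight sum drops below target
    for _ in range(64):
        s = np.exp(-shifted / hi[:, None]).sum(axis=1)
        grow = s < target
        if not grow.any():
            break
        hi[grow] *= 2.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        s = np.exp(-shifted / mid[:, None]).sum(axis=1)
        too_small = s < target
        lo = np.where(too_small, mid, lo)
        hi = np.where(too_small, hi, mid)
    sigma = 0.5 * (lo + hi)
    return np.exp(-shifted / sigma[:, None])


def build_knn_graph(rep, k: int, kernel: str = "exponential") -> NeighborGraph:
    """Build the union-symmetrized kNN graph of a representation.

    Parameters
    ----------
    rep
        A :class:`~pagamap.preprocess.Representation` or a plain
        (cells x comps) array.
    k
        Number of nearest neighbors per cell (1 <= k < n_cells).
    kernel
        One of ``exponential``, ``adaptive_gaussian``, ``unit``.
    """
    coords = np.asarray(getattr(rep, "coords", rep), dtype=float)
    cell_ids = getattr(rep, "cell_ids", None)
    n = coords.shape[0]
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}")
    idx, dist = exact_knn(coords, k)

    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    if kernel == "unit":
        w = np.ones(n * k)
    elif kernel == "exponential":
        w = _smooth_knn_weights(dist, k).ravel()
    else:  # adaptive_gaussian
        j = min(int(np.ceil(k / 2)), k) - 1
        sigma = np.maximum(dist[:, j], 1e-12)
        w = np.exp(-(dist**2) / (sigma[:, None] * sigma[cols].reshape(n, k)))
        w = w.ravel()
    w = np.clip(w, 1e-300, 1.0)

    directed_w = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    directed_d = sp.csr_matrix((dist.ravel() + 1e-300, (rows, cols)), shape=(n, n))
    weights = directed_w.maximum(directed_w.T)
    distances = directed_d.maximum(directed_d.T)
    weights.setdiag(0)
    weights.eliminate_zeros()
    distances.setdiag(0)
    distances.eliminate_zeros()
    return NeighborGraph(
        weights=weights.tocsr(),
        distances=distances.tocsr(),
        k=k,
        kernel=kernel,
        cell_ids=list(cell_ids) if cell_ids is not None else None,
    )


def graph_from_edges(
    edges: np.ndarray | list,
    n_cells: int,
    k: int = 1,
    kernel: str = "unit",
    cell_ids: list[str] | None = None,
) -> NeighborGraph:
    """Build a NeighborGraph directly from (u, v, weight) triples.

    Convenience constructor for tests and for ingesting externally built
    graphs; edges are symmetrized by max weight.
    """
    arr = np.asarray(list(edges), dtype=float)
    if arr.size == 0:
        w = sp.csr_matrix((n_cells, n_cells))
        return NeighborGraph(weights=w, distances=w.copy(), k=k, kernel=kernel, cell_ids=cell_ids)
    if arr.shape[1] == 2:
        arr = np.column_stack([arr, np.ones(len(arr))])
    u, v, w = arr[:, 0].astype(int), arr[:, 1].astype(int), arr[:, 2]
    m = sp.csr_matrix((w, (u, v)), shape=(n_cells, n_cells))
    m = m.maximum(m.T)
    m.setdiag(0)
    m.eliminate_zeros()
    d = m.copy()
    d.data = -np.log(np.clip(d.data, 1e-300, 1.0)) + 1e-300
    return NeighborGraph(weights=m.tocsr(), distances=d.tocsr(), k=k, kernel=kernel, cell_ids=cell_ids)
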