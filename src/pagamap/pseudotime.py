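"""Random-walk pseudotime on (possibly disconnected) neighborhood graphs.

Diffusion pseudotime measures how far a random walk started at a root
cell must spread to reach another cell: with S the density-corrected,
symmetrized transition operator and S = sum_i lambda_i phi_i phi_i^T its
spectral decomposition, the accumulated transition matrix

    M = sum_{lambda_i < 1} lambda_i / (1 - lambda_i) * phi_i phi_i^T

sums the walk over all path lengths after removing the stationary (unit)
eigenspace, and d(x, y) = ||M(x, .) - M(y, .)||_2.

On a disconnected graph the unit eigenspace has one dimension per
connected component; removing the whole subspace makes d well defined
within each component, and cells outside the root's component are
assigned an infinite distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

from .neighbors import NeighborGraph

INFINITE = np.inf
_UNIT_TOL = 1e-10


@dataclass
class TransitionMatrix:
    """Row-stochastic walk matrix plus its symmetric conjugate."""

    values: sp.csr_matrix  # row-stochastic T
    sym: sp.csr_matrix  # S = Z^{-1/2} K Z^{-1/2}, similar to T
    component_labels: np.ndarray
    n_components: int

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class SpectralDecomposition:
    """Descending eigenpairs of the symmetric transition operator."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns phi_i, orthonormal
    unit_eigenspace_dim: int


@dataclass
class DptResult:
    """Distances d from a root cell; infinite outside its component."""

    root: int
    d: np.ndarray
    n_comps_used: int
    component_labels: np.ndarray

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.d)


def transition_matrix(
    graph: NeighborGraph, density_correct: bool = True, include_self: bool = True
) -> TransitionMatrix:
    """Build the random-walk operator from the kernel-weighted graph.

    ``include_self`` adds the kernel's self-similarity K(x, x) = 1 on the
    diagonal (the Gaussian-kernel convention of diffusion maps); this
    keeps the spectrum away from -1 and makes pseudotime increase
    monotonically along one-dimensional manifolds.  Set it to False for
    the bare loop-free walk.  With density correction (diffusion-maps
    alpha=1) the kernel is divided by the product of endpoint degrees,
    removing sampling-density effects, before row normalization.
    Isolated cells become absorbing self-loops (flagged with a warning).
    """
    w = graph.weights.tocsr().astype(float)
    n = w.shape[0]
    if include_self:
        w = (w + sp.identity(n, format="csr")).tocsr()
    q = np.asarray(w.sum(axis=1)).ravel()
    isolated = q == 0
    if isolated.any():
        warnings.warn(f"{int(isolated.sum())} isolated cell(s); rows set to self-loops", stacklevel=2)
        w = w.tolil()
        for i in np.flatnonzero(isolated):
            w[i, i] = 1.0
        w = w.tocsr()
        q = np.asarray(w.sum(axis=1)).ravel()
    if density_correct:
        inv_q = 1.0 / q
        k = sp.diags(inv_q) @ w @ sp.diags(inv_q)
    else:
        k = w
    z = np.asarray(k.sum(axis=1)).ravel()
    t = sp.diags(1.0 / z) @ k
    inv_sqrt_z = 1.0 / np.sqrt(z)
    s = sp.diags(inv_sqrt_z) @ k @ sp.diags(inv_sqrt_z)
    n_comp, labels = connected_components(graph.weights, directed=False)
    return TransitionMatrix(values=t.tocsr(), sym=s.tocsr(), component_labels=labels, n_components=n_comp)


def spectral_decomposition(tm: TransitionMatrix, n_comps: int = 10) -> SpectralDecomposition:
    """Top eigenpairs of S: the full unit eigenspace plus n_comps more.

    Dense solve below ~1500 cells, Lanczos above.  Eigenvalues within
    1e-10 of 1 are classified as the unit eigenspace; its dimension equals
    the number of connected components.  Near-unit eigenvalues just below
    the tolerance are reported in a warning since they indicate weakly
    connected structure.
    """
    n = tm.n_cells
    want = min(n, tm.n_components + n_comps)
    if n <= 1500 or want >= n - 1:
        vals, vecs = np.linalg.eigh(tm.sym.toarray())
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    else:
        vals, vecs = eigsh(tm.sym, k=want, which="LA")
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    unit_dim = int(np.sum(vals >= 1.0 - _UNIT_TOL))
    near = np.sum((vals < 1.0 - _UNIT_TOL) & (vals > 1.0 - 1e-6))
    if near:
        warnings.warn(f"{int(near)} eigenvalue(s) within 1e-6 of 1: weakly connected structure", stacklevel=2)
    keep = min(len(vals), unit_dim + n_comps)
    return SpectralDecomposition(eigenvalues=vals[:keep], eigenvectors=vecs[:, :keep], unit_eigenspace_dim=unit_dim)


def dpt_distance(
    tm: TransitionMatrix,
    root: int,
    n_comps: int = 10,
    decomposition: SpectralDecomposition | None = None,
) -> DptResult:
    """Diffusion pseudotime from a root cell, infinite across components.

    ``n_comps`` counts eigenpairs beyond the unit eigenspace; it is
    truncated (with a warning) when the spectrum is smaller.
    """
    n = tm.n_cells
    if not 0 <= root < n:
        raise ValueError(f"root {root} outside [0, {n})")
    dec = decomposition or spectral_decomposition(tm, n_comps=n_comps)
    u = dec.unit_eigenspace_dim
    avail = dec.eigenvalues.size - u
    used = min(n_comps, avail)
    if used < n_comps:
        warnings.warn(f"only {used} non-unit eigenpairs available; truncated", stacklevel=2)
    lam = dec.eigenvalues[u : u + used]
    phi = dec.eigenvectors[:, u : u + used]
    scale = lam / (1.0 - lam)
    diff = (phi - phi[root]) * scale[None, :]
    d = np.sqrt((diff**2).sum(axis=1))
    mask = tm.component_labels != tm.component_labels[root]
    d[mask] = INFINITE
    d[root] = 0.0
    return DptResult(root=root, d=d, n_comps_used=used, component_labels=tm.component_labels)


def select_root(dpt_candidates: np.ndarray, tm: TransitionMatrix, group_mask: np.ndarray | None = None) -> int:
    """Pick a root as the cell with extremal first diffusion component.

    Restricted to ``group_mask`` when given (e.g. an annotated progenitor
    group).  ``dpt_candidates`` is unused except for its length and kept
    for signature stability.
    """
    dec = spectral_decomposition(tm, n_comps=1)
    u = dec.unit_eigenspace_dim
    if dec.eigenvalues.size <= u:
        raise ValueError("graph has no non-unit spectrum to select a root from")
    comp1 = dec.eigenvectors[:, u]
    idx = np.arange(tm.n_cells) if group_mask is None else np.flatnonzero(group_mask)
    return int(idx[np.argmax(np.abs(comp1[idx]))])


@dataclass
class PathTrace:
    """Cells of a PAGA path in trajectory order with gene expression."""

    table: "object"  # pandas.DataFrame: rank, cell_id, group, d, genes...
    smoothed: "object"  # pandas.DataFrame: same genes, sliding-window mean
    window: int


def trace_path(
    paga,
    path: list[int],
    part,
    dpt: DptResult,
    expr,
    genes: list[str] | None = None,
    window: int | None = None,
) -> PathTrace:
    """Order the cells of consecutive connected groups by distance d.

    ``path`` is a sequence of group ids whose consecutive pairs must be
    kept edges of ``paga``; within each group cells are sorted by their
    pseudotime d, and per-gene sliding-window means smooth the resulting
    single-cell expression profile.
    """
    import pandas as pd

    for a, b in zip(path[:-1], path[1:]):
        pair = (min(a, b), max(a, b))
        if pair not in {tuple(e) for e in paga.edges_kept}:
            raise ValueError(f"groups {a} and {b} are not connected in the abstracted graph")
    labels = part.labels
    order: list[int] = []
    for g in path:
        members = np.flatnonzero(labels == g)
        if not np.all(np.isfinite(dpt.d[members])):
            raise ValueError(f"group {g} is disconnected from the root's component; cannot order by d")
        order.extend(members[np.argsort(dpt.d[members], kind="stable")].tolist())
    order = np.asarray(order)

    gene_ids = list(getattr(expr, "gene_ids", [str(i) for i in range(np.asarray(getattr(expr, "values", expr)).shape[1])]))
    values = np.asarray(getattr(expr, "values", expr))
    genes = genes or gene_ids
    cols = [gene_ids.index(g) for g in genes]
    cell_ids = getattr(expr, "cell_ids", None) or [str(i) for i in range(values.shape[0])]

    table = pd.DataFrame(
        {
            "rank": np.arange(len(order)),
            "cell_id": [cell_ids[i] for i in order],
            "group": labels[order],
            "d": dpt.d[order],
        }
    )
    for name, c in zip(genes, cols):
        table[name] = values[order, c]
    w = window or max(5, len(order) // 50)
    smoothed = table[genes].rolling(window=w, center=True, min_periods=1).mean()
    return PathTrace(table=table, smoothed=smoothed, window=w)
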