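"""Evaluation measures: geodesic-distance KL divergence and topology score.

``kl_geo`` quantifies how faithful an embedding is to the global topology
of the high-dimensional data: geodesic (graph shortest-path) distances
between a sample of cells are computed on the high-dimensional kNN graph
and on a kNN graph built in the embedding, each normalized into a
distribution over cell pairs, and compared with a KL divergence.  Zero
means the two geodesic structures are proportional.

``topology_path_score`` compares two abstracted graphs through their path
sets: for every pair of leaf nodes of the reference, the shortest paths
in both graphs (after mapping inferred groups onto reference nodes by
majority cell overlap) must visit the same reference-node sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .abstraction import AbstractionTree, PagaGraph
from .neighbors import NeighborGraph

INFINITE = np.inf


@dataclass
class GeodesicDistances:
    """Pairwise shortest-path distances over a sampled cell subset."""

    D: np.ndarray
    sample_ids: np.ndarray
    source_space: str = "highdim_graph"
    edge_length: str = "neglog"


@dataclass
class TopologyScore:
    """Fraction of reference leaf pairs whose paths are consistent."""

    score: float
    n_path_pairs: int
    per_pair_detail: list = field(default_factory=list)


def geodesic_distances(
    graph: NeighborGraph,
    sample_size: int = 500,
    seed: int = 0,
    source_space: str = "highdim_graph",
    edge_length: str = "neglog",
) -> GeodesicDistances:
    """All-pairs shortest paths over a uniform random cell sample.

    ``edge_length='neglog'`` maps kernel weights in (0, 1] to lengths
    -log(w) (clipped below at 1e-12) so strong edges are short;
    ``'unit'`` uses hop counts.  Entries across connected components are
    infinite.
    """
    n = graph.n_cells
    if sample_size > n:
        raise ValueError("sample_size exceeds number of cells")
    rng = np.random.default_rng(seed)
    sample = np.sort(rng.choice(n, size=sample_size, replace=False))
    lengths = graph.weights.copy().astype(float)
    if edge_length == "neglog":
        lengths.data = np.clip(-np.log(np.clip(lengths.data, 1e-300, 1.0)), 1e-12, None)
    elif edge_length == "unit":
        lengths.data = np.ones_like(lengths.data)
    else:
        raise ValueError("edge_length must be 'neglog' or 'unit'")
    d = dijkstra(lengths, directed=False, indices=sample)
    return GeodesicDistances(D=d[:, sample], sample_ids=sample, source_space=source_space, edge_length=edge_length)


def _pair_values(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(D.shape[0], k=1)
    return D[iu]


def kl_geo(
    high: GeodesicDistances,
    emb: GeodesicDistances,
    transform: str = "identity",
    symmetrized: bool = False,
) -> float:
    """KL divergence between geodesic-distance distributions.

    Pairs finite in both spaces are normalized to distributions P (high
    dimensional) and Q (embedding); D_KL(P || Q) is returned (averaged
    with the reverse direction when ``symmetrized``).  ``transform``
    optionally maps distances through a Gaussian kernel of bandwidth equal
    to the median distance before normalizing.  Scale-invariant: equal or
    proportional distance matrices give 0.
    """
    if not np.array_equal(high.sample_ids, emb.sample_ids):
        raise ValueError("geodesic distances computed on different samples")
    p = _pair_values(high.D)
    q = _pair_values(emb.D)
    mask = np.isfinite(p) & np.isfinite(q)
    if not mask.any():
        raise ValueError("no cell pair is connected in both spaces; KL_geo undefined")
    p, q = p[mask], q[mask]
    if transform == "gaussian":
        sp_, sq_ = np.median(p[p > 0]) if (p > 0).any() else 1.0, np.median(q[q > 0]) if (q > 0).any() else 1.0
        p = np.exp(-(p**2) / (2 * sp_**2))
        q = np.exp(-(q**2) / (2 * sq_**2))
    elif transform != "identity":
        raise ValueError("transform must be 'identity' or 'gaussian'")
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("degenerate all-zero distances; KL_geo undefined")
    p = p / p.sum()
    q = np.clip(q / q.sum(), 1e-300, None)

    def _kl(a: np.ndarray, b: np.ndarray) -> float:
        m = a > 0
        return float(np.sum(a[m] * np.log(a[m] / b[m])))

    if symmetrized:
        return 0.5 * (_kl(p, q) + _kl(q, p))
    return _kl(p, q)


def _as_nx(graph: PagaGraph | AbstractionTree | nx.Graph) -> nx.Graph:
    if isinstance(graph, nx.Graph):
        g = nx.Graph()
        g.add_nodes_from(sorted(graph.nodes()))
        g.add_edges_from(sorted(tuple(sorted(e)) for e in graph.edges()))
        return g
    g = nx.Graph()
    if isinstance(graph, AbstractionTree):
        g.add_nodes_from(range(graph.n_groups))
        g.add_edges_from(sorted(graph.edges))
    else:
        g.add_nodes_from(range(graph.n_groups))
        g.add_edges_from(sorted(tuple(e) for e in graph.edges_kept))
    return g


def _collapse(seq: list) -> tuple:
    out = []
    for x in seq:
        if not out or out[-1] != x:
            out.append(x)
    return tuple(out)


def _support_sets(cell_association, min_overlap: float):
    """Per inferred group: majority reference node, and the support set of
    reference nodes holding at least ``min_overlap`` of its cells."""
    majority: dict[int, int] = {}
    strength: dict[int, float] = {}
    support: dict[int, frozenset] = {}
    if isinstance(cell_association, np.ndarray):
        frac = cell_association
        for g in range(frac.shape[0]):
            r = int(np.argmax(frac[g]))
            majority[g], strength[g] = r, float(frac[g, r])
            support[g] = frozenset({r} | set(np.flatnonzero(frac[g] >= min_overlap).tolist()))
    else:
        for g, v in cell_association.items():
            r, s = (int(v[0]), float(v[1])) if isinstance(v, tuple) else (int(v), 1.0)
            majority[g], strength[g] = r, s
            support[g] = frozenset({r})
    return majority, strength, support


def _covers_in_order(sets: list, ref_path: tuple) -> bool:
    """True if ref_path is an in-order subsequence of the support sets
    (one set may cover several consecutive reference nodes)."""
    i = 0
    for s in sets:
        while i < len(ref_path) and ref_path[i] in s:
            i += 1
    return i == len(ref_path)


def topology_path_score(
    reference: PagaGraph | AbstractionTree | nx.Graph,
    inferred: PagaGraph | AbstractionTree | nx.Graph,
    cell_association,
    min_overlap: float = 0.05,
) -> TopologyScore:
    """Compare two abstracted graphs through their leaf-pair path sets.

    ``cell_association`` relates inferred groups to reference nodes:
    either a dict {inferred: reference} / {inferred: (reference, overlap)}
    (e.g. :func:`pagamap.abstraction.map_resolutions`) or a row-normalized
    overlap-fraction matrix (:func:`pagamap.abstraction.overlap_fractions`),
    which additionally exposes secondary memberships of groups straddling
    a junction.

    For every pair of reference leaves (degree <= 1; all nodes when fewer
    than two leaves exist) the shortest path between the best-matching
    inferred groups is computed in the inferred graph and mapped back:
    each visited group contributes the set of reference nodes holding at
    least ``min_overlap`` of its cells.  The pair is consistent when the
    reference shortest-path node sequence appears in order along those
    sets and no off-path reference node is visited.  With clean
    one-to-one associations this reduces to requiring the identical
    reference-node sequence (contiguous duplicates collapsed).
    """
    ref = _as_nx(reference)
    inf_g = _as_nx(inferred)
    majority, strength, support = _support_sets(
        cell_association if isinstance(cell_association, np.ndarray) else dict(cell_association),
        min_overlap,
    )

    # best inferred representative of each reference node
    rep: dict[int, int] = {}
    for g in sorted(inf_g.nodes()):
        if g not in majority:
            continue
        r = majority[g]
        if r not in rep or strength[g] > strength[rep[r]]:
            rep[r] = g

    leaves = sorted(n for n in ref.nodes() if ref.degree(n) <= 1)
    if len(leaves) < 2:
        leaves = sorted(ref.nodes())
    pairs = [(a, b) for i, a in enumerate(leaves) for b in leaves[i + 1 :]]
    detail = []
    n_ok = 0
    for a, b in pairs:
        entry = {"pair": (a, b), "consistent": False, "reason": ""}
        ref_has = nx.has_path(ref, a, b)
        if a not in rep or b not in rep:
            entry["reason"] = "unmappable endpoint"
            detail.append(entry)
            continue
        ia, ib = rep[a], rep[b]
        inf_has = nx.has_path(inf_g, ia, ib)
        if ref_has != inf_has:
            entry["reason"] = "connectivity mismatch"
            detail.append(entry)
            continue
        if not ref_has:
            entry["consistent"] = True
            entry["reason"] = "both disconnected"
            n_ok += 1
            detail.append(entry)
            continue
        ref_path = _collapse(nx.shortest_path(ref, a, b))
        inf_path = nx.shortest_path(inf_g, ia, ib)
        if any(g not in majority for g in inf_path):
            entry["reason"] = "unmappable group on path"
            detail.append(entry)
            continue
        sets = [support[g] for g in inf_path]
        # only groups cleanly inside one reference node can violate the
        # path; junction groups legitimately mix adjacent segments
        pure_visited = {next(iter(s)) for s in sets if len(s) == 1}
        if not _covers_in_order(sets, ref_path):
            entry["reason"] = f"reference sequence {ref_path} not covered in order"
        elif not pure_visited <= set(ref_path):
            entry["reason"] = f"off-path reference nodes visited: {sorted(pure_visited - set(ref_path))}"
        else:
            entry["consistent"] = True
            n_ok += 1
        detail.append(entry)
    score = 1.0 if not pairs else n_ok / len(pairs)
    return TopologyScore(score=score, n_path_pairs=len(pairs), per_pair_detail=detail)
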