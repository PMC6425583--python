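import numpy as np
import pytest

import pagamap as pm
from pagamap.abstraction import (
    connectivity_directed,
    connectivity_undirected,
    count_inter_edges,
    expected_null,
    map_resolutions,
    overlap_fractions,
    spanning_tree,
    threshold_graph,
)
from pagamap.neighbors import build_knn_graph, graph_from_edges
from pagamap.partition import Partitioning


def part_of(labels):
    return Partitioning(labels=np.asarray(labels), source="external")


def clique_edges(nodes):
    return [(u, v, 1.0) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]


class TestCountInterEdges:
    def test_complete_graph_split_in_half_counts_cross_edges(self):
        g = graph_from_edges(clique_edges([0, 1, 2, 3]), n_cells=4)
        c = count_inter_edges(g, part_of([0, 0, 1, 1]))
        assert c.e[0, 1] == 4  # exhaustive: (0,2),(0,3),(1,2),(1,3)
        assert c.e_total == 6

    def test_disjoint_cliques_have_zero_inter_edges(self):
        g = graph_from_edges(clique_edges([0, 1, 2]) + clique_edges([3, 4, 5]), n_cells=6)
        c = count_inter_edges(g, part_of([0, 0, 0, 1, 1, 1]))
        assert c.e[0, 1] == 0

    def test_single_group_gives_one_by_one_zero_matrix(self):
        g = graph_from_edges(clique_edges([0, 1, 2]), n_cells=3)
        c = count_inter_edges(g, part_of([0, 0, 0]))
        assert c.e.shape == (1, 1) and c.e[0, 0] == 0

    def test_weighted_counting_sums_edge_weights(self):
        g = graph_from_edges([(0, 1, 0.5), (1, 2, 0.25)], n_cells=3)
        c = count_inter_edges(g, part_of([0, 1, 1]), use_weights=True)
        assert c.e[0, 1] == 0.5

    def test_counts_match_igraph_cluster_graph(self):
        # independent cross-check against igraph's own cluster aggregation
        import igraph as ig

        rng = np.random.default_rng(7)
        n = 30
        edges = [(i, j, 1.0) for i in range(n) for j in range(i + 1, n) if rng.uniform() < 0.2]
        g = graph_from_edges(edges, n_cells=n)
        labels = rng.integers(0, 4, size=n)
        labels[:4] = [0, 1, 2, 3]
        part = part_of(labels)
        c = count_inter_edges(g, part)

        gi = ig.Graph(n=n, edges=[(int(u), int(v)) for u, v, _ in g.edge_array()])
        vc = ig.VertexClustering(gi, membership=list(part.labels))
        cg = vc.cluster_graph(combine_edges="sum")
        for e in cg.es:
            i, j = e.tuple
            if i != j:
                assert c.e[i, j] == pytest.approx(len(gi.es.select(_between=(vc[i], vc[j]))))


class TestConnectivityUndirected:
    def test_worked_example_four_cells_two_pairs(self):
        # path 0-1-2-3, groups {0,1} and {2,3}: one inter-edge, k=1
        g = graph_from_edges([(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)], n_cells=4)
        part = part_of([0, 0, 1, 1])
        paga = connectivity_undirected(count_inter_edges(g, part), part, k=1)
        assert paga.expected[0, 1] == pytest.approx(4.0 / 3.0)
        assert paga.theta[0, 1] == pytest.approx(0.75)

    def test_zero_inter_edges_give_zero_connectivity(self):
        g = graph_from_edges(clique_edges([0, 1, 2]) + clique_edges([3, 4, 5]), n_cells=6)
        part = part_of([0, 0, 0, 1, 1, 1])
        paga = connectivity_undirected(count_inter_edges(g, part), part, k=2)
        assert paga.theta[0, 1] == 0.0

    def test_ratio_capped_at_one(self):
        g = graph_from_edges(clique_edges([0, 1, 2, 3]), n_cells=4)
        part = part_of([0, 0, 1, 1])
        paga = connectivity_undirected(count_inter_edges(g, part), part, k=1)
        assert paga.theta[0, 1] == 1.0  # e=4 far above e^=4/3

    def test_degenerate_null_warns_and_sets_theta_one(self):
        g = graph_from_edges([(0, 1, 1.0)], n_cells=2)
        part = part_of([0, 1])
        c = count_inter_edges(g, part)
        with pytest.warns(UserWarning, match="degenerate"):
            paga = connectivity_undirected(c, part, k=1, null=lambda *_: np.zeros((2, 2)))
        assert paga.theta[0, 1] == 1.0

    def test_permutation_equivariance_of_theta(self):
        rng = np.random.default_rng(3)
        edges = [(i, j, 1.0) for i in range(12) for j in range(i + 1, 12) if rng.uniform() < 0.4]
        g = graph_from_edges(edges, n_cells=12)
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3])
        perm = np.array([2, 0, 3, 1])  # group relabeling
        part_a = part_of(labels)
        part_b = part_of(perm[labels])
        ta = connectivity_undirected(count_inter_edges(g, part_a), part_a, k=3).theta
        tb = connectivity_undirected(count_inter_edges(g, part_b), part_b, k=3).theta
        np.testing.assert_allclose(tb[np.ix_(perm, perm)], ta)

    def test_theta_monotone_in_observed_inter_edges(self):
        # add one more inter-edge, everything else fixed
        base = [(0, 1, 1.0), (2, 3, 1.0), (1, 2, 1.0)]
        more = base + [(0, 3, 1.0)]
        part = part_of([0, 0, 1, 1])
        thetas = []
        for edges in (base, more):
            g = graph_from_edges(edges, n_cells=4)
            thetas.append(connectivity_undirected(count_inter_edges(g, part), part, k=2).theta[0, 1])
        assert thetas[1] >= thetas[0]

    def test_matches_bruteforce_on_small_random_graphs(self):
        # exhaustive-style oracle: explicit loops over edges and components
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            k = int(rng.integers(1, 4))
            adj = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.uniform() < 0.5:
                        adj[i, j] = adj[j, i] = 1.0
            labels = rng.integers(0, min(3, n), size=n)
            labels = np.unique(labels, return_inverse=True)[1]
            g = graph_from_edges(
                [(i, j, 1.0) for i in range(n) for j in range(i + 1, n) if adj[i, j]], n_cells=n
            )
            part = part_of(labels)
            theta = connectivity_undirected(count_inter_edges(g, part), part, k=k).theta

            comp = _bruteforce_components(adj)
            for a in range(part.n_groups):
                for b in range(a + 1, part.n_groups):
                    e_ab = sum(
                        adj[i, j]
                        for i in range(n)
                        for j in range(i + 1, n)
                        if {labels[i], labels[j]} == {a, b}
                    )
                    comps = {comp[i] for i in range(n) if labels[i] in (a, b)}
                    nc = sum(1 for i in range(n) if comp[i] in comps)
                    na, nb = (labels == a).sum(), (labels == b).sum()
                    ehat = k * na * nb / (nc - 1) if nc > 1 else 0.0
                    want = 0.0 if e_ab == 0 else (1.0 if ehat == 0 else min(1.0, e_ab / ehat))
                    assert abs(theta[a, b] - want) <= 1e-12

    def test_disconnected_group_leaves_other_entries_bit_identical(self):
        ds = pm.simulate_tree(pm.y_topology(), cells_per_segment=100, seed=0)
        g1 = build_knn_graph(ds.expr, k=10)
        from pagamap.partition import partition_graph

        part1 = partition_graph(g1, seed=0)
        theta1 = connectivity_undirected(count_inter_edges(g1, part1), part1, k=10).theta

        ds2 = pm.add_disconnected_cluster(ds, n_cells=50, seed=1)
        g2 = build_knn_graph(ds2.expr, k=10)
        labels2 = np.concatenate([part1.labels, np.full(50, part1.n_groups)])
        part2 = part_of(labels2)
        paga2 = connectivity_undirected(count_inter_edges(g2, part2), part2, k=10)
        G = part1.n_groups
        assert np.array_equal(paga2.theta[:G, :G], theta1)
        assert paga2.theta[G].max() == 0.0
        # sensitivity: the global-n null does not have this invariance
        tg1 = connectivity_undirected(count_inter_edges(g1, part1), part1, k=10, null="knn_global").theta
        tg2 = connectivity_undirected(count_inter_edges(g2, part2), part2, k=10, null="knn_global").theta
        assert not np.array_equal(tg2[:G, :G], tg1)

    def test_degree_null_formula(self):
        g = graph_from_edges([(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)], n_cells=4)
        part = part_of([0, 0, 1, 1])
        c = count_inter_edges(g, part)
        ehat = expected_null(c, k=1, null="degrees")
        # d_0 = 2*1 intra + 1 inter = 3; d_1 = 3; e^ = (3*2+3*2)/(2*3) = 2
        assert ehat[0, 1] == pytest.approx(2.0)


def _bruteforce_components(adj):
    n = adj.shape[0]
    comp = [-1] * n
    c = 0
    for s in range(n):
        if comp[s] >= 0:
            continue
        stack = [s]
        while stack:
            u = stack.pop()
            if comp[u] >= 0:
                continue
            comp[u] = c
            stack.extend(v for v in range(n) if adj[u, v] and comp[v] < 0)
        c += 1
    return comp


class TestConnectivityDirected:
    def test_all_forward_arrows_give_tendency_one(self):
        part = part_of([0, 0, 1, 1])
        pg = connectivity_directed([(0, 2, 1.0), (1, 3, 1.0)], part)
        assert pg.directed_tendency[0, 1] == 1.0
        assert pg.directed_tendency[1, 0] == -1.0

    def test_balanced_arrows_give_zero_tendency(self):
        part = part_of([0, 1])
        pg = connectivity_directed([(0, 1, 1.0), (1, 0, 1.0)], part)
        assert pg.directed_tendency[0, 1] == 0.0

    def test_three_to_one_ratio_gives_half(self):
        part = part_of([0, 0, 0, 1, 1, 1])
        arrows = [(0, 3, 1.0), (1, 4, 1.0), (2, 5, 1.0), (3, 0, 1.0)]
        pg = connectivity_directed(arrows, part)
        assert pg.directed_tendency[0, 1] == pytest.approx(0.5)

    def test_empty_velocity_graph_warns_all_zero(self):
        part = part_of([0, 1])
        with pytest.warns(UserWarning, match="empty"):
            pg = connectivity_directed([], part)
        assert np.all(pg.directed_tendency == 0)

    def test_antisymmetry_and_base_carryover(self, y_result):
        part = y_result["partition"]
        rng = np.random.default_rng(0)
        arrows = [(int(a), int(b), 1.0) for a, b in rng.integers(0, part.n_cells, size=(200, 2)) if a != b]
        pg = connectivity_directed(arrows, part, base=y_result["thresholded"])
        t = pg.directed_tendency
        np.testing.assert_allclose(t, -t.T)
        np.testing.assert_array_equal(pg.theta, y_result["thresholded"].theta)
        assert pg.edges_kept == y_result["thresholded"].edges_kept
        assert len(pg.oriented_edges()) == len(pg.edges_kept)


class TestThresholdAndTree:
    def _paga(self, theta, e=None):
        from pagamap.abstraction import PagaGraph

        theta = np.asarray(theta, dtype=float)
        e = theta.copy() if e is None else np.asarray(e, dtype=float)
        g = theta.shape[0]
        return PagaGraph(
            theta=theta, expected=np.ones_like(theta), inter_edges=e,
            group_sizes=np.ones(g, dtype=int), edges_kept=[],
        )

    def test_threshold_zero_keeps_all_pairs_with_observed_edges(self):
        paga = self._paga([[0, 0.5, 0], [0.5, 0, 0.2], [0, 0.2, 0]])
        out = threshold_graph(paga, 0.0)
        assert set(out.edges_kept) == {(0, 1), (1, 2)}

    def test_threshold_one_keeps_only_capped_edges(self):
        paga = self._paga([[0, 1.0, 0], [1.0, 0, 0.2], [0, 0.2, 0]])
        out = threshold_graph(paga, 1.0)
        assert set(out.edges_kept) == {(0, 1)}

    def test_kept_set_shrinks_monotonically_with_threshold(self, y_result):
        low = threshold_graph(y_result["paga"], 0.0)
        high = threshold_graph(y_result["paga"], 0.5)
        assert set(high.edges_kept) <= set(low.edges_kept)

    def test_threshold_out_of_range_rejected(self, y_result):
        with pytest.raises(ValueError):
            threshold_graph(y_result["paga"], 1.5)

    def test_chain_topology_tree_drops_weak_closing_edge(self):
        # exhaustive on 3 nodes: strong A-B, B-C; weak A-C
        paga = self._paga([[0, 0.9, 0.1], [0.9, 0, 0.8], [0.1, 0.8, 0]])
        paga = threshold_graph(paga, 0.0)
        tree = spanning_tree(paga)
        assert set(tree.edges) == {(0, 1), (1, 2)}

    def test_equal_weight_triangle_breaks_ties_lexicographically(self):
        paga = self._paga(np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]))
        paga = threshold_graph(paga, 0.0)
        tree = spanning_tree(paga)
        assert tree.edges == [(0, 1), (0, 2)]

    def test_disconnected_groups_yield_forest(self):
        paga = self._paga(np.zeros((2, 2)))
        paga = threshold_graph(paga, 0.0)
        tree = spanning_tree(paga)
        assert tree.edges == []
        assert tree.n_groups == 2


class TestMapResolutions:
    def test_identity_mapping_has_full_overlap(self):
        p = part_of([0, 0, 1, 1, 2])
        assoc = map_resolutions(p, p)
        assert assoc == {0: (0, 1.0), 1: (1, 1.0), 2: (2, 1.0)}

    def test_majority_rule_with_sixty_forty_split(self):
        fine = part_of([0] * 10)
        coarse = part_of([0] * 6 + [1] * 4)
        assoc = map_resolutions(fine, coarse)
        assert assoc[0] == (0, pytest.approx(0.6))

    def test_nested_partitions_recover_planted_hierarchy(self):
        coarse_labels = np.repeat([0, 1], 20)
        fine_labels = np.repeat([0, 1, 2, 3], 10)
        assoc = map_resolutions(part_of(fine_labels), part_of(coarse_labels))
        assert {k: v[0] for k, v in assoc.items()} == {0: 0, 1: 0, 2: 1, 3: 1}
        assert all(v[1] == 1.0 for v in assoc.values())

    def test_overlap_fraction_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        fine = part_of(np.unique(rng.integers(0, 5, 50), return_inverse=True)[1])
        coarse = part_of(np.unique(rng.integers(0, 3, 50), return_inverse=True)[1])
        frac = overlap_fractions(fine, coarse)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0)
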