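"""Modularity, Louvain unfolding, community structure, meta-networks."""
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from vasculotopo.community_analysis import (
    MetaNetwork,
    build_meta_network,
    community_structure,
    filter_isolated_communities,
    fit_assortativity,
    fit_isolation_exponent,
    louvain_unfold,
    meta_topology,
    modularity,
    path_length_vs_separation,
)


def brute_force_modularity(g, assignment, weight=None):
    """Direct double-sum evaluation with A_ii = 2w for self-loops."""
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        w = 1.0 if weight is None else d.get(weight, 1.0)
        i, j = idx[u], idx[v]
        if i == j:
            A[i, i] += 2 * w
        else:
            A[i, j] += w
            A[j, i] += w
    k = A.sum(axis=1)
    m2 = A.sum()  # = 2m
    q = 0.0
    for i in range(n):
        for j in range(n):
            if assignment[nodes[i]] == assignment[nodes[j]]:
                q += A[i, j] - k[i] * k[j] / m2
    return q / m2


class TestModularity:
    def test_single_community_zero(self, bridge_graph):
        assert modularity(bridge_graph, {n: 0 for n in bridge_graph}) == pytest.approx(0.0, abs=1e-14)

    def test_bridge_two_cliques(self, bridge_graph):
        assignment = {n: (0 if n < 5 else 1) for n in bridge_graph}
        q = modularity(bridge_graph, assignment)
        assert q == pytest.approx(2 * (10 / 21 - (21 / 42) ** 2), abs=1e-12)

    def test_singletons(self, bridge_graph):
        q = modularity(bridge_graph, {n: n for n in bridge_graph})
        assert q == pytest.approx(-178 / 1764, abs=1e-12)

    def test_brute_force_agreement_random_graphs(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            g = nx.gnm_random_graph(20, 45, seed=int(rng.integers(1e6)))
            g = nx.MultiGraph(g)
            g.add_edge(0, 0)  # exercise the self-loop convention
            g.add_edge(1, 2)  # and a parallel edge
            assignment = {n: int(rng.integers(4)) for n in g}
            assert modularity(g, assignment) == pytest.approx(
                brute_force_modularity(g, assignment), abs=1e-12
            )

    def test_weighted(self):
        g = nx.Graph()
        g.add_edge(0, 1, w=3.0)
        g.add_edge(2, 3, w=1.0)
        g.add_edge(1, 2, w=0.5)
        assignment = {0: 0, 1: 0, 2: 1, 3: 1}
        assert modularity(g, assignment, weight="w") == pytest.approx(
            brute_force_modularity(g, assignment, weight="w"), abs=1e-12
        )

    def test_empty_edge_set_rejected(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1])
        with pytest.raises(ValueError):
            modularity(g, {0: 0, 1: 1})

    def test_unassigned_node_rejected(self, bridge_graph):
        with pytest.raises(ValueError):
            modularity(bridge_graph, {0: 0})


class TestLouvain:
    def test_bridge_reaches_global_optimum(self, bridge_graph):
        # exhaustive bipartition search confirms 0.45238 is the 2-way optimum
        nodes = list(bridge_graph)
        best = max(
            modularity(bridge_graph, {n: (1 if n in side else 0) for n in nodes})
            for r in range(1, 6)
            for side in map(set, itertools.combinations(nodes, r))
        )
        part = louvain_unfold(bridge_graph, seed=0)
        assert best == pytest.approx(2 * (10 / 21 - (21 / 42) ** 2), abs=1e-12)
        assert part.q_final == pytest.approx(best, abs=1e-9)

    def test_ring_of_cliques_matches_clique_partition(self):
        g = nx.ring_of_cliques(16, 5)
        # Eq-direct value of the 16-clique partition: each clique has 10
        # internal edges and degree sum 22 of 2m = 352
        q_cliques = 16 * (10 / 176 - (22 / 352) ** 2)
        assignment = {n: n // 5 for n in g}
        assert modularity(g, assignment) == pytest.approx(q_cliques, abs=1e-12)
        part = louvain_unfold(g, seed=0)
        assert abs(part.q_final - q_cliques) <= 0.02

    def test_q_nondecreasing_over_levels(self, healthy_mini):
        *_, graph = healthy_mini
        part = louvain_unfold(graph, seed=0, restarts=2)
        qs = [q for _, q in part.levels]
        assert all(b >= a - 1e-12 for a, b in zip(qs, qs[1:]))
        assert part.q_final >= 0.0

    def test_no_community_spans_disconnected_halves(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        part = louvain_unfold(g, seed=0)
        for c in part.communities().values():
            assert c <= set(range(6)) or c <= set(range(6, 12))

    def test_deterministic_given_seed(self, bridge_graph):
        a = louvain_unfold(bridge_graph, seed=3)
        b = louvain_unfold(bridge_graph, seed=3)
        assert a.final == b.final and a.q_final == b.q_final

    def test_planted_partition_recovered(self):
        g = nx.planted_partition_graph(2, 100, 0.5, 0.01, seed=5)
        part = louvain_unfold(g, seed=0)
        comms = list(part.communities().values())
        assert len(comms) == 2
        assert {frozenset(c) for c in comms} == {
            frozenset(range(100)), frozenset(range(100, 200))
        }

    def test_edgeless_rejected(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1])
        with pytest.raises(ValueError):
            louvain_unfold(g, seed=0)


class TestCommunityStructure:
    def test_centroid_and_extent(self):
        g = nx.Graph()
        g.add_node(0, pos_um=np.array([0.0, 0.0, 0.0]))
        g.add_node(1, pos_um=np.array([2.0, 0.0, 0.0]))
        g.add_edge(0, 1)
        rec = community_structure(g, {0: 0, 1: 0})
        assert np.allclose(rec.loc[0, ["centroid_z", "centroid_y", "centroid_x"]], [1, 0, 0])
        assert rec.loc[0, "R_um"] == pytest.approx(1.0)

    def test_community_degree_identity(self, bridge_graph):
        assignment = {n: (0 if n < 5 else 1) for n in bridge_graph}
        rec = community_structure(bridge_graph, assignment)
        assert (rec["k_c"] == 2 * rec["e"] + rec["P"]).all()
        assert (rec["e"] == 10).all() and (rec["P"] == 1).all()
        assert (rec["e_over_P"] == 10).all()

    def test_bookkeeping_identities(self, healthy_mini):
        *_, graph = healthy_mini
        part = louvain_unfold(graph, seed=1, restarts=2)
        rec = community_structure(graph, part.final)
        assert rec["n"].sum() == graph.n_nodes
        meta = build_meta_network(graph, part.final)
        assert rec["e"].sum() + meta.n_intercommunity_edges == graph.n_edges
        assert rec["P"].sum() == 2 * meta.n_intercommunity_edges


class TestFilterIsolated:
    def test_small_isolated_removed_connected_kept(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.path_graph(6))
        g.add_edges_from([(3, 100), (4, 100)])  # attach a neighbour community
        assignment = {n: 0 for n in range(3)}
        assignment.update({n: 1 for n in range(3, 9)})
        assignment[100] = 2
        kept, log = filter_isolated_communities(g, assignment, min_edges=20)
        assert 0 not in set(kept.values())  # isolated triangle: e=3 < 20, P=0
        assert 1 in set(kept.values())  # has perimeter, kept regardless of e
        assert log["n_removed"] == 1

    def test_min_edges_zero_identity(self, bridge_graph):
        assignment = {n: (0 if n < 5 else 1) for n in bridge_graph}
        kept, log = filter_isolated_communities(bridge_graph, assignment, min_edges=0)
        assert kept == assignment and log["n_removed"] == 0


class TestMetaNetwork:
    def test_bridge_meta(self, bridge_graph):
        assignment = {n: (0 if n < 5 else 1) for n in bridge_graph}
        meta = build_meta_network(bridge_graph, assignment)
        assert meta.n_communities == 2
        assert meta.graph.number_of_edges() == 1
        assert meta.graph[0][1]["weight"] == 1
        assert meta.n_intercommunity_edges == 1

    def test_triangle_weights(self):
        g = nx.Graph()
        for c, base in enumerate([0, 10, 20]):
            g.add_edges_from([(base + i, base + i + 1) for i in range(4)])
        # two crossing segments per community pair
        g.add_edges_from([(0, 10), (1, 11), (10, 20), (11, 21), (20, 0), (21, 1)])
        assignment = {n: n // 10 for n in g}
        meta = build_meta_network(g, assignment)
        assert meta.graph.number_of_edges() == 3
        assert all(d["weight"] == 2 for _, _, d in meta.graph.edges(data=True))
        assert meta.n_intercommunity_edges == 6

    def test_meta_topology_triangle_and_path(self):
        tri = nx.complete_graph(3)
        for n in tri:
            tri.nodes[n].update(k_c=10, centroid_z=0.0, centroid_y=0.0, centroid_x=float(n))
        stats = meta_topology(MetaNetwork(tri, pd.DataFrame(), 3))
        assert stats["C_c"] == 1.0 and stats["L_c"] == 1.0 and stats["D_c"] == 1.0
        path = nx.path_graph(3)
        for n in path:
            path.nodes[n].update(k_c=10, centroid_z=0.0, centroid_y=0.0, centroid_x=float(n))
        stats = meta_topology(MetaNetwork(path, pd.DataFrame(), 2))
        assert stats["L_c"] == pytest.approx(4 / 3) and stats["D_c"] == 2


class TestCommunityFits:
    def test_isolation_exact_recovery(self):
        e = np.arange(10, 200)
        rec = pd.DataFrame({"e": e, "P": 2.0 * e**0.99})
        fit = fit_isolation_exponent(rec)
        assert abs(fit.exponent - 0.99) <= 0.01

    def test_isolation_flat(self):
        rec = pd.DataFrame({"e": np.arange(10, 100), "P": np.full(90, 7.0)})
        assert abs(fit_isolation_exponent(rec).exponent) < 1e-6

    def test_isolation_degenerate_flagged(self):
        rec = pd.DataFrame({"e": [5, 6], "P": [1, 2]})
        assert not fit_isolation_exponent(rec).ok

    def test_assortativity_star_negative(self):
        g = nx.star_graph(10)
        g.nodes[0]["k_c"] = 100.0
        for n in range(1, 11):
            g.nodes[n]["k_c"] = 10.0
        fit = fit_assortativity(MetaNetwork(g, pd.DataFrame(), 10))
        assert fit.exponent < -0.5

    def test_assortativity_regular_ring_zero(self):
        g = nx.cycle_graph(12)
        for n in g:
            g.nodes[n]["k_c"] = 50.0
        fit = fit_assortativity(MetaNetwork(g, pd.DataFrame(), 12))
        assert abs(fit.exponent) < 1e-6

    def test_assortativity_generative_recovery(self):
        # stars whose hubs carry k_c = 3 sqrt(L): every leaf sits exactly on
        # <k_c1>(k_c) = 3 k_c^0.5, hubs are a small off-curve minority that
        # the bisquare weights reject
        rng = np.random.default_rng(0)
        g = nx.Graph()
        nid = 0
        for _ in range(30):
            L = 10 ** rng.uniform(1, 3)
            hub = nid
            g.add_node(hub, k_c=float(3.0 * np.sqrt(L)))
            nid += 1
            for _ in range(10):
                g.add_node(nid, k_c=float(L))
                g.add_edge(hub, nid)
                nid += 1
        fit = fit_assortativity(MetaNetwork(g, pd.DataFrame(), 300))
        assert abs(fit.exponent - 0.5) <= 0.05


class TestPathLengthVsSeparation:
    @staticmethod
    def _meta(nodes, edges):
        g = nx.Graph()
        for n, (z, y, x) in nodes.items():
            g.add_node(n, k_c=1, centroid_z=z, centroid_y=y, centroid_x=x)
        g.add_edges_from(edges)
        return MetaNetwork(g, pd.DataFrame(), len(edges))

    def test_adjacent_pair_single_bin(self):
        meta = self._meta({0: (0, 0, 0), 1: (0, 0, 120.0)}, [(0, 1)])
        df = path_length_vs_separation(meta, delta_um=50.0)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["bin_lo_um"] == 100.0 and row["mean_L_c"] == 1.0 and row["n_pairs"] == 1

    def test_two_hop_pair(self):
        meta = self._meta(
            {0: (0, 0, 0.0), 1: (0, 0, 100.0), 2: (0, 0, 200.0)}, [(0, 1), (1, 2)]
        )
        df = path_length_vs_separation(meta, delta_um=50.0)
        far = df[df["bin_lo_um"] == 200.0]
        assert far["mean_L_c"].iloc[0] == 2.0
        assert df["n_pairs"].sum() == 3  # all connected pairs binned

    def test_counts_sum_to_connected_pairs(self, healthy_mini):
        *_, graph = healthy_mini
        part = louvain_unfold(graph, seed=2, restarts=2)
        meta = build_meta_network(graph, part.final)
        df = path_length_vs_separation(meta)
        n_connected = sum(
            len(c) * (len(c) - 1) // 2
            for c in nx.connected_components(meta.graph)
        )
        assert df["n_pairs"].sum() == n_connected
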