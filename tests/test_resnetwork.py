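"""Residue networks: contact rule, betweenness, communication pathways."""

import itertools
import logging
from collections import deque

import networkx as nx
import numpy as np
import pytest

import allodyn as ad
from allodyn.resnetwork import floyd_warshall

from conftest import point_structure


def net_from_graph(G, chains=None):
    """Wrap an abstract graph as a ResidueNetwork (coordinates are dummies)."""
    n = G.number_of_nodes()
    coords = np.column_stack([np.arange(n) * 50.0, np.zeros(n), np.zeros(n)])
    s = point_structure(coords, chains)
    H = nx.Graph()
    H.add_nodes_from(range(n))
    H.add_edges_from(G.edges)
    return ad.ResidueNetwork(s, np.zeros((n, n)), 6.5, 0.5, H)


def bfs_distances(G, source):
    """Plain breadth-first-search distances (independent oracle)."""
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in G.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def brute_force_bc(G):
    """Enumerate every shortest path of every pair; fractional credit."""
    n = G.number_of_nodes()
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        dist = bfs_distances(G, t)
        if s not in dist:
            continue
        paths = []

        def walk(u, acc):
            if u == t:
                paths.append(list(acc))
                return
            for v in G.neighbors(u):
                if dist.get(v, -1) == dist[u] - 1:
                    walk(v, acc + [v])

        walk(s, [s])
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


class TestBuildNetwork:
    def test_contact_cutoff_boundary(self):
        for d, expect in ((6.4, True), (6.6, False)):
            s = point_structure([[0, 0, 0], [d, 0, 0]], chains=["A", "B"])
            traj = ad.Trajectory(s.ca_coords[None], s, aligned=True)
            net = ad.build_network(traj, backbone_guarantee=False)
            assert net.graph.has_edge(0, 1) is expect

    def test_occupancy_thresholding(self):
        s = point_structure([[0, 0, 0], [5, 0, 0]], chains=["A", "B"])
        frames = np.array([
            [[0, 0, 0], [5, 0, 0]],
            [[0, 0, 0], [5, 0, 0]],
            [[0, 0, 0], [5, 0, 0]],
            [[0, 0, 0], [20, 0, 0]],
        ], dtype=float)
        traj = ad.Trajectory(frames, s, aligned=True)
        net = ad.build_network(traj, occupancy_threshold=0.5,
                               backbone_guarantee=False)
        assert net.edge_occupancy[0, 1] == 0.75
        assert net.graph.has_edge(0, 1)
        strict = ad.build_network(traj, occupancy_threshold=0.8,
                                  backbone_guarantee=False)
        assert not strict.graph.has_edge(0, 1)

    def test_cb_nodes_used_where_present(self, complex24):
        traj = ad.Trajectory(complex24.ca_coords[None], complex24, aligned=True)
        net = ad.build_network(traj)
        # occupancy must reflect Cβ-else-Cα geometry, not Cα alone
        from scipy.spatial.distance import pdist, squareform

        expected = squareform(pdist(complex24.node_coords()) <= 6.5).astype(float)
        occ = net.edge_occupancy.copy()
        np.testing.assert_array_equal(occ, expected)

    def test_backbone_guarantee_bridges_gaps(self, caplog):
        s = point_structure([[0, 0, 0], [8, 0, 0], [16, 0, 0]])
        traj = ad.Trajectory(s.ca_coords[None], s, aligned=True)
        with caplog.at_level(logging.INFO, logger="allodyn.resnetwork"):
            net = ad.build_network(traj)
        assert net.graph.has_edge(0, 1) and net.graph.has_edge(1, 2)
        assert any("backbone" in r.message for r in caplog.records)
        # but never across chains
        s2 = point_structure([[0, 0, 0], [8, 0, 0]], chains=["A", "B"])
        traj2 = ad.Trajectory(s2.ca_coords[None], s2, aligned=True)
        assert not ad.build_network(traj2).graph.has_edge(0, 1)


class TestBetweenness:
    def test_star_hub(self):
        G = nx.star_graph(4)  # node 0 is the hub
        bc = ad.betweenness(net_from_graph(G))
        np.testing.assert_allclose(bc, [6.0, 0, 0, 0, 0])

    def test_complete_graph(self):
        bc = ad.betweenness(net_from_graph(nx.complete_graph(4)))
        np.testing.assert_array_equal(bc, 0.0)

    def test_four_cycle_fractional_credit(self):
        bc = ad.betweenness(net_from_graph(nx.cycle_graph(4)))
        np.testing.assert_allclose(bc, 0.5)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            G = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            bc = ad.betweenness(net_from_graph(G))
            np.testing.assert_allclose(bc, brute_force_bc(G), atol=1e-9)

    def test_frame_average_variant(self, complex24):
        traj = ad.Trajectory(
            np.repeat(complex24.ca_coords[None], 3, axis=0), complex24, aligned=True
        )
        net = ad.build_network(traj)
        static = ad.betweenness(net)
        averaged = ad.betweenness(net, frame_average=True)
        assert averaged.shape == static.shape
        assert (averaged >= 0).all()


class TestShortestPaths:
    def test_floyd_warshall_matches_bfs(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            G = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2**31)))
            D = floyd_warshall(net_from_graph(G))
            for s in range(n):
                dist = bfs_distances(G, s)
                for t in range(n):
                    expect = dist.get(t, np.inf)
                    assert D[s, t] == expect

    def test_adjacent_pair_single_edge(self):
        G = nx.path_graph(3)
        paths = ad.shortest_paths(net_from_graph(G), 0, 1)
        assert len(paths) == 1
        assert paths[0].n_edges == 1

    def test_four_cycle_two_paths_lexicographic(self):
        paths = ad.shortest_paths(net_from_graph(nx.cycle_graph(4)), 0, 2)
        assert [p.residues for p in paths] == [
            ["A:1", "A:2", "A:3"],
            ["A:1", "A:4", "A:3"],
        ]
        assert all(p.n_edges == 2 for p in paths)

    def test_unreachable_sink_empty_with_warning(self, caplog):
        G = nx.Graph()
        G.add_nodes_from(range(4))
        G.add_edge(0, 1)
        with caplog.at_level(logging.WARNING, logger="allodyn.resnetwork"):
            paths = ad.shortest_paths(net_from_graph(G), 0, 3)
        assert paths == []
        assert any("unreachable" in r.message for r in caplog.records)

    def test_source_equals_sink_rejected(self):
        with pytest.raises(ValueError):
            ad.shortest_paths(net_from_graph(nx.path_graph(3)), 1, 1)

    def test_max_paths_cap(self):
        G = nx.complete_bipartite_graph(2, 6)  # many equal-length 0→1 paths
        paths = ad.shortest_paths(net_from_graph(G), 0, 1, max_paths=3)
        assert len(paths) == 3

    def test_bridges_mark_interchain_steps(self):
        G = nx.path_graph(4)
        net = net_from_graph(G, chains=["A", "A", "B", "B"])
        (path,) = ad.shortest_paths(net, 0, 3)
        assert path.bridges == [("A:2", "B:1")]

    def test_insertion_order_independence(self):
        edges = [(0, 1), (1, 2), (2, 3), (0, 4), (4, 3)]
        a = net_from_graph(nx.Graph(edges))
        b = net_from_graph(nx.Graph(list(reversed(edges))))
        pa = [p.residues for p in ad.shortest_paths(a, 0, 3)]
        pb = [p.residues for p in ad.shortest_paths(b, 0, 3)]
        assert pa == pb

    def test_edge_removal_never_shortens_distances(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            G = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(2**31)))
            if G.number_of_edges() == 0:
                continue
            D = floyd_warshall(net_from_graph(G))
            H = G.copy()
            edge = list(H.edges)[int(rng.integers(H.number_of_edges()))]
            H.remove_edge(*edge)
            D2 = floyd_warshall(net_from_graph(H))
            assert (D2 >= D - 1e-12).all()


class TestCompareBc:
    def test_identical_networks_zero_delta(self, complex24):
        traj = ad.Trajectory(complex24.ca_coords[None], complex24, aligned=True)
        net = ad.build_network(traj)
        sel = ad.ResidueSelection(frozenset([0, 5, 12]), "sites")
        table = ad.compare_bc(net, net, sel)
        assert (table["delta_bc"] == 0).all()
        assert not table["missing"].any()

    def test_new_bridge_raises_bc(self):
        G = nx.path_graph(5)
        H = G.copy()
        H.add_edge(0, 3)  # node 3 now bridges a new unique shortcut 0-3-4
        sel = ad.ResidueSelection(frozenset([3]), "s")
        table = ad.compare_bc(net_from_graph(G), net_from_graph(H), sel)
        assert table.loc[0, "delta_bc"] > 0

    def test_unmatched_label_flagged(self, complex24, globule20):
        net_a = ad.build_network(
            ad.Trajectory(complex24.ca_coords[None], complex24, aligned=True)
        )
        net_b = ad.build_network(
            ad.Trajectory(globule20.ca_coords[None], globule20, aligned=True)
        )
        # complex24 chain B labels do not exist in the single-chain globule
        b_start = complex24.chain_slices()["B"].start
        sel = ad.ResidueSelection(frozenset([0, b_start]), "mixed")
        table = ad.compare_bc(net_a, net_b, sel)
        assert table["missing"].tolist() == [False, True]
        assert len(table) == 2
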