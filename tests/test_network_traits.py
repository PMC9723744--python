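import itertools
import math

import networkx as nx
import numpy as np
import pytest

from myconet.core import attach_root, edge_resistance
from myconet.network_traits import (
    area_normalized_efficiencies,
    geff_mst,
    global_efficiency,
    meshedness,
    minimum_spanning_tree,
    network_traits,
    root_efficiency,
    root_tip_efficiency,
    shortest_path_distances,
    volume_mst,
)

from conftest import make_net, random_connected_net


def width_for_resistance(length, resistance, alpha=4):
    """Invert r = l / (w/2)^alpha."""
    return 2.0 * (length / resistance) ** (1.0 / alpha)


class TestShortestPaths:
    def test_unit_path(self, unit_resistance_path):
        d = shortest_path_distances(unit_resistance_path, [0])[0]
        assert d[2] == pytest.approx(2.0)
        assert d[0] == 0.0

    def test_triangle_detour_wins(self):
        """Resistances 1, 1, 3: crossing the heavy edge directly loses to the detour."""
        net = make_net({0: (0.0, 0.0), 1: (1.0, 0.0), 2: (0.5, 0.9)},
                       [(0, 1, 1.0, 2.0), (1, 2, 1.0, 2.0),
                        (0, 2, 1.0, width_for_resistance(1.0, 3.0))])
        d = shortest_path_distances(net, [0])[0]
        assert d[2] == pytest.approx(2.0)

    def test_matches_floyd_warshall_oracle(self):
        """Repeated Dijkstra equals a dense all-pairs oracle on random graphs."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            net = random_connected_net(rng, n_nodes=15, extra_edges=6)
            order = sorted(net.nodes)
            n = len(order)
            dense = np.full((n, n), np.inf)
            np.fill_diagonal(dense, 0.0)
            res = net.edge_resistances()
            for eid, e in net.edges.items():
                i, j = order.index(e.u), order.index(e.v)
                dense[i, j] = dense[j, i] = min(dense[i, j], res[eid])
            for k in range(n):  # Floyd-Warshall
                dense = np.minimum(dense, dense[:, [k]] + dense[[k], :])
            got = shortest_path_distances(net, order)
            for i, s in enumerate(order):
                for j, t in enumerate(order):
                    assert got[s][t] == pytest.approx(dense[i, j])


class TestEfficiencies:
    def test_root_efficiency_path(self, unit_resistance_path):
        assert root_efficiency(unit_resistance_path) == pytest.approx(0.75)

    def test_root_tip_star(self):
        """Three tips at resistance 2 each -> RT_eff = 0.5."""
        coords = {0: (0.0, 0.0)}
        edges = []
        for i in range(3):
            coords[i + 1] = (math.cos(i), math.sin(i))
            edges.append((0, i + 1, 2.0, 2.0))  # r = 2/1 = 2
        net = make_net(coords, edges, root=0)
        assert root_tip_efficiency(net) == pytest.approx(0.5)

    def test_width_halving_scales_efficiency(self, unit_resistance_path):
        """Halving every width multiplies resistances x16 (micro) so R_eff x1/16."""
        base = root_efficiency(unit_resistance_path)
        for e in unit_resistance_path.edges.values():
            e.width /= 2.0
        assert root_efficiency(unit_resistance_path) == pytest.approx(base / 16.0)

    def test_global_efficiency_unit_triangle(self, unit_triangle):
        assert global_efficiency(unit_triangle) == pytest.approx(1.0)

    def test_global_efficiency_path(self, unit_resistance_path):
        """(1 + 1 + 1/2) / 3 pairs — the root here is an endpoint-free node,
        so use an unrooted copy of the same chain."""
        net = make_net({0: (0.0, 0.0), 1: (1.0, 0.0), 2: (2.0, 0.0)},
                       [(0, 1, 1.0, 2.0), (1, 2, 1.0, 2.0)])
        assert global_efficiency(net) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_adding_edge_never_decreases_geff(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            net = random_connected_net(rng, n_nodes=10, extra_edges=2)
            before = global_efficiency(net)
            i, j = 0, int(rng.integers(1, 10))
            net.add_edge(i, j, float(rng.uniform(1, 5)), float(rng.uniform(1, 5)))
            assert global_efficiency(net) >= before - 1e-12


class TestMST:
    def test_triangle_keeps_light_edges(self):
        net = make_net({0: (0.0, 0.0), 1: (1.0, 0.0), 2: (0.5, 0.9)},
                       [(0, 1, 1.0, width_for_resistance(1.0, 1.0)),
                        (1, 2, 1.0, width_for_resistance(1.0, 2.0)),
                        (0, 2, 1.0, width_for_resistance(1.0, 3.0))])
        tree = minimum_spanning_tree(net)
        assert sorted(tree.edges) == [0, 1]

    def test_idempotent_on_trees(self):
        rng = np.random.default_rng(1)
        net = random_connected_net(rng, n_nodes=8, extra_edges=0)
        tree = minimum_spanning_tree(net)
        assert sorted(tree.edges) == sorted(net.edges)

    def test_exhaustive_enumeration_small_graphs(self):
        """Kruskal equals brute-force minimum over all spanning trees (<= 6 nodes)."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            net = random_connected_net(rng, n_nodes=6, extra_edges=4)
            res = net.edge_resistances()
            ids = list(net.edges)
            n = net.n_nodes
            best = math.inf
            for combo in itertools.combinations(ids, n - 1):
                g = nx.Graph()
                g.add_nodes_from(net.nodes)
                for eid in combo:
                    g.add_edge(net.edges[eid].u, net.edges[eid].v)
                if g.number_of_edges() == n - 1 and nx.is_connected(g):
                    best = min(best, sum(res[i] for i in combo))
            tree = minimum_spanning_tree(net)
            assert sum(res[i] for i in tree.edges) == pytest.approx(best)

    def test_beats_random_spanning_trees(self):
        rng = np.random.default_rng(17)
        net = random_connected_net(rng, n_nodes=12, extra_edges=8)
        res = net.edge_resistances()
        mst_cost = sum(res[i] for i in minimum_spanning_tree(net).edges)
        g = nx.MultiGraph()
        for eid, e in net.edges.items():
            g.add_edge(e.u, e.v, key=eid)
        for _ in range(50):
            # random spanning tree via randomized Kruskal
            ids = list(net.edges)
            rng.shuffle(ids)
            uf = {n: n for n in net.nodes}
            def find(i):
                while uf[i] != i:
                    uf[i] = uf[uf[i]]
                    i = uf[i]
                return i
            cost, count = 0.0, 0
            for eid in ids:
                e = net.edges[eid]
                ru, rv = find(e.u), find(e.v)
                if ru != rv:
                    uf[rv] = ru
                    cost += res[eid]
                    count += 1
            assert count == net.n_nodes - 1
            assert mst_cost <= cost + 1e-12


class TestMeshedness:
    def test_tree_is_zero(self):
        rng = np.random.default_rng(2)
        net = random_connected_net(rng, n_nodes=9, extra_edges=0)
        assert meshedness(net) == 0.0

    def test_four_cycle(self):
        net = make_net({0: (0.0, 0.0), 1: (1.0, 0.0), 2: (1.0, 1.0), 3: (0.0, 1.0)},
                       [(0, 1, 1.0, 1.0), (1, 2, 1.0, 1.0),
                        (2, 3, 1.0, 1.0), (3, 0, 1.0, 1.0)])
        assert meshedness(net) == pytest.approx(1 / 3)

    def test_maximal_planar_five_nodes(self):
        """K5 minus one edge: E = 3N - 6 = 9 -> meshedness 1."""
        coords = {0: (0.0, 0.0), 1: (4.0, 0.0), 2: (2.0, 3.0), 3: (2.0, 1.0), 4: (2.0, -2.0)}
        pairs = [p for p in itertools.combinations(range(5), 2) if p != (3, 4)]
        net = make_net(coords, [(u, v, 1.0, 1.0) for u, v in pairs])
        assert meshedness(net) == pytest.approx(1.0)

    def test_matches_cycle_rank_oracle(self):
        """(E - N + C) via networkx component count on random graphs."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            net = random_connected_net(rng, n_nodes=12, extra_edges=5)
            g = nx.MultiGraph()
            for e in net.measured_edges():
                g.add_edge(e.u, e.v)
            rank = g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)
            assert meshedness(net) == pytest.approx(rank / (2 * g.number_of_nodes() - 5))

    def test_removing_nonbridge_edge_decreases_meshedness(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            net = random_connected_net(rng, n_nodes=10, extra_edges=4)
            g = nx.MultiGraph()
            for eid, e in net.edges.items():
                g.add_edge(e.u, e.v, key=eid)
            bridges = set()
            simple = nx.Graph(g)
            for u, v in nx.bridges(simple):
                if g.number_of_edges(u, v) == 1:
                    ks = list(g[u][v])
                    bridges.add(ks[0])
            non_bridge = [eid for eid in net.edges if eid not in bridges]
            if not non_bridge:
                continue
            before_m = meshedness(net)
            before_g = global_efficiency(net)
            net.remove_edge(non_bridge[0])
            assert meshedness(net) < before_m
            assert global_efficiency(net) <= before_g + 1e-12


class TestMSTRatios:
    def test_tree_input_ratios_one(self):
        rng = np.random.default_rng(4)
        net = random_connected_net(rng, n_nodes=8, extra_edges=0)
        assert volume_mst(net) == pytest.approx(1.0)
        assert geff_mst(net) == pytest.approx(1.0)

    def test_equal_triangle_volume_ratio(self):
        """Three equal edges (l=1, w=2): volume 3*pi vs MST 2*pi -> 1.5."""
        net = make_net({0: (0.0, 0.0), 1: (1.0, 0.0), 2: (0.5, 0.9)},
                       [(0, 1, 1.0, 2.0), (1, 2, 1.0, 2.0), (0, 2, 1.0, 2.0)])
        assert volume_mst(net) == pytest.approx(1.5)

    def test_geff_ratio_at_least_one(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            net = random_connected_net(rng, n_nodes=10, extra_edges=4)
            assert geff_mst(net) >= 1.0 - 1e-12
            assert volume_mst(net) >= 1.0 - 1e-12


class TestAreaNormalization:
    def test_division_by_area(self):
        net = make_net({0: (0.0, 0.0), 1: (1.0, 0.0), 2: (0.0, 1.0)},
                       [(0, 1, 1.0, 2.0), (0, 2, 1.0, 2.0)], root=0)
        r, rt = area_normalized_efficiencies(net)
        assert r == pytest.approx(root_efficiency(net) / 0.5)
        assert rt == pytest.approx(root_tip_efficiency(net) / 0.5)

    def test_size_correction_tracks_magnification(self):
        """Characterization: under coordinate scaling x s (widths fixed, micro),
        hull area grows s^2 while resistances grow s, so R_eff_area ~ s^-3."""
        from myconet.synthetic import SynthParams, grow_network

        net = grow_network(SynthParams(seed=5, n_steps=20))
        base_r, _ = area_normalized_efficiencies(net)
        s = 2.0
        for node in net.nodes.values():
            node.xy = (node.xy[0] * s, node.xy[1] * s)
        for e in net.edges.values():
            e.length *= s
            e.polyline = None
        scaled_r, _ = area_normalized_efficiencies(net)
        assert scaled_r == pytest.approx(base_r / s ** 3, rel=1e-6)


def test_network_traits_bundle(unit_triangle):
    """The bundled computation agrees with the individual trait functions."""
    net = unit_triangle
    attach_root(net, (0.5, 0.3), [0])
    t = network_traits(net)
    assert t.G_eff == pytest.approx(global_efficiency(net))
    assert t.meshedness == pytest.approx(meshedness(net))
    assert t.volume_MST == pytest.approx(volume_mst(net))
    assert 0 <= t.meshedness <= 1
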