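import numpy as np
import pytest

from myconet.core import MycelialNetwork


def make_net(coords, edges, root=None, root_edges=(), scale="micro"):
    """Hand-build a network.

    coords: {node_id: (x, y)}; edges: [(u, v, length, width), ...];
    root: node id to designate as the Root (may sit on a measured node);
    root_edges: indices into `edges` to flag as synthetic root edges.
    """
    net = MycelialNetwork(scale)
    for nid, xy in coords.items():
        net.add_node(xy, node_id=nid)
    for i, (u, v, length, width) in enumerate(edges):
        net.add_edge(u, v, length, width, is_root_edge=i in set(root_edges))
    if root is not None:
        net.root_id = root
    net.classify_nodes()
    return net


@pytest.fixture
def unit_resistance_path():
    """root - a - b chain, every edge resistance 1 (length 1, width 2, micro)."""
    return make_net({0: (0.0, 0.0), 1: (1.0, 0.0), 2: (2.0, 0.0)},
                    [(0, 1, 1.0, 2.0), (1, 2, 1.0, 2.0)], root=0)


@pytest.fixture
def unit_triangle():
    """K3 with all resistances 1; no root."""
    return make_net({0: (0.0, 0.0), 1: (1.0, 0.0), 2: (0.5, 0.9)},
                    [(0, 1, 1.0, 2.0), (1, 2, 1.0, 2.0), (0, 2, 1.0, 2.0)])


def random_connected_net(rng, n_nodes=15, extra_edges=5, scale="micro"):
    """Random connected network: spanning tree + extra chords."""
    net = MycelialNetwork(scale)
    pts = rng.uniform(0, 100, (n_nodes, 2))
    for i in range(n_nodes):
        net.add_node(pts[i], node_id=i)
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        net.add_edge(i, j, float(rng.uniform(1, 10)), float(rng.uniform(1, 5)))
    added = 0
    while added < extra_edges:
        i, j = rng.integers(0, n_nodes, 2)
        if i != j:
            net.add_edge(int(i), int(j), float(rng.uniform(1, 10)),
                         float(rng.uniform(1, 5)))
            added += 1
    return net
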