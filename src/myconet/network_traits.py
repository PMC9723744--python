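"""Network connectivity traits (traits 6–10).

All transport computations run on the resistance-weighted graph:
edge weight = length / (width/2)^alpha, alpha 4 (micro) or 2 (macro).
Efficiency between two nodes is the reciprocal of their shortest-path
resistance distance, so thin/long routes are inefficient and short/wide
routes efficient.  The Root node and its synthetic edges are part of the
path graph (they are the inoculum's connection) but the Root is never an
endpoint in global efficiency and root edges never enter edge counts or
volume sums.

The minimum spanning tree (MST), computed on the same resistances, is
the minimal-cost backbone that still reaches every node; ratios against
it (G_eff/G_eff(MST), volume/volume(MST)) index how much a colony
over-builds relative to the cheapest transport skeleton.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra

from .core import MycelialNetwork
from .morphology import mycelial_area


@dataclass
class NetTraits:
    meshedness: float
    R_eff: float
    RT_eff: float | None
    G_eff: float
    G_eff_MST: float
    volume_MST: float
    R_eff_area: float
    RT_eff_area: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "meshedness": self.meshedness,
            "R_eff": self.R_eff,
            "RT_eff": self.RT_eff,
            "G_eff": self.G_eff,
            "G_eff_MST": self.G_eff_MST,
            "volume_MST": self.volume_MST,
            "R_eff_area": self.R_eff_area,
            "RT_eff_area": self.RT_eff_area,
        }


# ------------------------------------------------------------- path machinery

def _node_order(net: MycelialNetwork) -> list[int]:
    return sorted(net.nodes)


def _resistance_csr(net: MycelialNetwork, order: Sequence[int]) -> sp.csr_matrix:
    """Sparse symmetric resistance matrix; parallel edges keep the smaller one."""
    idx = {nid: i for i, nid in enumerate(order)}
    n = len(order)
    best: dict[tuple[int, int], float] = {}
    res = net.edge_resistances()
    for eid, e in net.edges.items():
        i, j = idx[e.u], idx[e.v]
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        r = res[eid]
        if key not in best or r < best[key]:
            best[key] = r
    if not best:
        return sp.csr_matrix((n, n))
    rows, cols, vals = [], [], []
    for (i, j), r in best.items():
        rows += [i, j]
        cols += [j, i]
        vals += [r, r]
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def shortest_path_distances(net: MycelialNetwork,
                            sources: Iterable[int]) -> dict[int, dict[int, float]]:
    """Single-source shortest-path resistance distances from each source.

    Returns ``{source: {node: distance}}``; unreachable nodes map to inf.
    """
    order = _node_order(net)
    idx = {nid: i for i, nid in enumerate(order)}
    graph = _resistance_csr(net, order)
    src = list(sources)
    dist = dijkstra(graph, directed=False, indices=[idx[s] for s in src])
    return {s: {order[j]: float(dist[i, j]) for j in range(len(order))}
            for i, s in enumerate(src)}


def _root_distances(net: MycelialNetwork) -> dict[int, float]:
    if net.root_id is None:
        raise ValueError("network has no Root; call attach_root first")
    return shortest_path_distances(net, [net.root_id])[net.root_id]


def root_efficiency(net: MycelialNetwork) -> float:
    """Mean over non-root nodes of 1 / resistance-distance(root, node).

    Unreachable nodes contribute zero efficiency.
    """
    d = _root_distances(net)
    vals = [1.0 / v if 0 < v < math.inf else 0.0
            for nid, v in d.items() if nid != net.root_id]
    if not vals:
        raise ValueError("no non-root nodes")
    return float(np.mean(vals))


def root_tip_efficiency(net: MycelialNetwork) -> float | None:
    """Root efficiency restricted to hyphal tips; None when there are no tips."""
    tips = net.tip_nodes()
    if not tips:
        return None
    d = _root_distances(net)
    vals = [1.0 / d[t] if 0 < d[t] < math.inf else 0.0 for t in tips]
    return float(np.mean(vals))


def global_efficiency(net: MycelialNetwork) -> float:
    """Mean over unordered non-root node pairs of 1 / resistance-distance.

    The Root and its edges stay in the path graph (routes may pass
    through the inoculum) but the Root is excluded as an endpoint.
    """
    order = _node_order(net)
    graph = _resistance_csr(net, order)
    keep = np.array([nid != net.root_id for nid in order])
    if keep.sum() < 2:
        raise ValueError("global efficiency needs at least 2 non-root nodes")
    dist = dijkstra(graph, directed=False, indices=np.flatnonzero(keep))
    sub = dist[:, keep]
    iu = np.triu_indices(sub.shape[0], k=1)
    d = sub[iu]
    with np.errstate(divide="ignore"):
        eff = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(eff.mean())


# ----------------------------------------------------------------------- MST

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_tree(net: MycelialNetwork) -> MycelialNetwork:
    """Spanning tree minimizing total resistance (deterministic Kruskal).

    Root edges, when present, are retained unconditionally — the
    inoculum connection is identical in the observed network and its MST
    baseline.  Ties among measured edges break by (resistance, length,
    edge id) ascending, making the tree unique.
    """
    order = _node_order(net)
    idx = {nid: i for i, nid in enumerate(order)}
    graph = _resistance_csr(net, order)
    n_comp, _ = connected_components(graph, directed=False)
    if len(order) > 1 and n_comp > 1:
        raise ValueError("minimum_spanning_tree requires a connected network")

    res = net.edge_resistances()
    uf = _UnionFind(len(order))
    keep: list[int] = []
    for e in net.root_edges():
        if uf.union(idx[e.u], idx[e.v]):
            keep.append(e.id)
    for eid in sorted((e.id for e in net.measured_edges()),
                      key=lambda i: (res[i], net.edges[i].length, i)):
        e = net.edges[eid]
        if uf.union(idx[e.u], idx[e.v]):
            keep.append(eid)

    tree = net.copy()
    for eid in list(tree.edges):
        if eid not in keep:
            tree.remove_edge(eid)
    return tree


# ------------------------------------------------------------------ topology

def _measured_counts(net: MycelialNetwork) -> tuple[int, int, int]:
    nodes: set[int] = set()
    n_edges = 0
    uf: dict[int, int] = {}

    def find(i: int) -> int:
        while uf[i] != i:
            uf[i] = uf[uf[i]]
            i = uf[i]
        return i

    for e in net.measured_edges():
        for nid in (e.u, e.v):
            if nid not in uf:
                uf[nid] = nid
        ru, rv = find(e.u), find(e.v)
        if ru != rv:
            uf[rv] = ru
        nodes.update((e.u, e.v))
        n_edges += 1
    n_comp = sum(1 for nid in uf if find(nid) == nid)
    return n_edges, len(nodes), n_comp


def meshedness(net: MycelialNetwork) -> float:
    """Planar meshedness: cycle-space rank / (2N - 5) over measured edges.

    The rank is E - N + C (C = connected components of the measured
    subgraph, which is a forest of inoculum-rooted trees when there are
    no anastomoses), so trees score 0 and maximal planar graphs 1.  For
    a connected measured graph this is the textbook (E - N + 1)/(2N - 5).
    """
    e, n, c = _measured_counts(net)
    if n < 3:
        raise ValueError("meshedness undefined for networks with fewer than 3 nodes")
    return (e - n + c) / (2 * n - 5)


def _measured_volume(net: MycelialNetwork) -> float:
    return sum(e.volume() for e in net.measured_edges())


def volume_mst(net: MycelialNetwork) -> float:
    """Relative construction cost: built hyphal volume / MST volume (>= 1)."""
    tree = minimum_spanning_tree(net)
    v_tree = _measured_volume(tree)
    if v_tree <= 0:
        raise ValueError("MST has zero measured volume")
    return _measured_volume(net) / v_tree


def geff_mst(net: MycelialNetwork) -> float:
    """Global-efficiency gain over the MST baseline (>= 1)."""
    return global_efficiency(net) / global_efficiency(minimum_spanning_tree(net))


def area_normalized_efficiencies(net: MycelialNetwork) -> tuple[float, float | None]:
    """(R_eff, RT_eff) divided by colony hull area — the size-corrected
    variants admissible when comparing colonies of different scales."""
    area = mycelial_area(net)
    if area <= 0:
        raise ValueError("degenerate (zero) mycelial area")
    r = root_efficiency(net) / area
    rt = root_tip_efficiency(net)
    return r, (rt / area if rt is not None else None)


def network_traits(net: MycelialNetwork) -> NetTraits:
    """Traits 6–10 plus the area-normalized efficiency variants."""
    r_eff = root_efficiency(net)
    rt_eff = root_tip_efficiency(net)
    area = mycelial_area(net)
    return NetTraits(
        meshedness=meshedness(net),
        R_eff=r_eff,
        RT_eff=rt_eff,
        G_eff=global_efficiency(net),
        G_eff_MST=geff_mst(net),
        volume_MST=volume_mst(net),
        R_eff_area=r_eff / area,
        RT_eff_area=rt_eff / area if rt_eff is not None else None,
    )
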