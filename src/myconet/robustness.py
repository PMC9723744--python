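"""Robustness of root-connectivity under fungivory-style attacks (traits 11–15).

Five edge-removal schemes mimic different grazers: random single bites,
random localized chunks (a grazer eating a patch), and targeted feeding
on the thinnest, widest or longest hyphae.  After each bite we measure
the fraction of mycelial *length* still connected to the inoculum Root;
robustness is the fraction of measured edges that must be removed before
that connected fraction first drops to 50% or below.  Root edges are
never removed and never counted in the length sums.

Reported as a fraction of edges (size-independent); the raw removal
count is also retained.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np

from .core import MycelialNetwork

SCHEME_NAMES = ("random_single", "random_chunk", "ascending_width",
                "descending_width", "descending_length")

#: trait-table column name per scheme
SCHEME_COLUMNS = {
    "random_single": "rob_random_single",
    "random_chunk": "rob_random_chunk",
    "ascending_width": "rob_asc_width",
    "descending_width": "rob_desc_width",
    "descending_length": "rob_desc_length",
}


@dataclass
class AttackScheme:
    name: str
    chunk_k: int | None = None     # edges per bite (random_chunk); default 2% of E
    replicates: int = 100          # for the stochastic schemes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown attack scheme {self.name!r}")
        if self.chunk_k is not None and self.chunk_k < 2:
            raise ValueError("chunk_k must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def stochastic(self) -> bool:
        return self.name in ("random_single", "random_chunk")

    def effective_chunk_k(self, n_edges: int) -> int:
        if self.chunk_k is not None:
            return min(self.chunk_k, n_edges)
        return min(max(2, round(0.02 * n_edges)), n_edges)


@dataclass
class RobustnessResult:
    scheme: str
    robustness: float                     # mean fraction of edges removed at crossing
    per_replicate: list[float]
    removed_counts: list[int]             # raw counts at crossing, per replicate
    trajectory: np.ndarray                # mean connected fraction after removing 1..E edges
    n_edges: int


def _measured_edge_ids(net: MycelialNetwork) -> list[int]:
    ids = [e.id for e in net.measured_edges()]
    if not ids:
        raise ValueError("network has no measured edges to attack")
    return ids


def attack_order(net: MycelialNetwork, scheme: AttackScheme) -> list[list[int]]:
    """Edge-removal orders, one flat list per replicate.

    Deterministic schemes return a single replicate.  For random_chunk
    the list is a concatenation of bites of ``chunk_k`` edges each (the
    final bite may be smaller); connectivity is assessed per bite.
    Ties among targeted schemes break by (width, length, id).
    """
    if net.root_id is None:
        raise ValueError("attach a Root before simulating attacks")
    ids = _measured_edge_ids(net)
    edges = net.edges

    if scheme.name == "ascending_width":
        return [sorted(ids, key=lambda i: (edges[i].width, edges[i].length, i))]
    if scheme.name == "descending_width":
        return [sorted(ids, key=lambda i: (-edges[i].width, edges[i].length, i))]
    if scheme.name == "descending_length":
        return [sorted(ids, key=lambda i: (-edges[i].length, edges[i].width, i))]

    rng = np.random.default_rng(scheme.seed)
    if scheme.name == "random_single":
        return [list(np.array(ids)[rng.permutation(len(ids))])
                for _ in range(scheme.replicates)]

    # random_chunk: a random edge plus its chunk_k-1 nearest remaining
    # neighbours by midpoint distance, repeated until nothing is left
    mid = np.array([_midpoint(net, edges[i]) for i in ids])
    k = scheme.effective_chunk_k(len(ids))
    ids_arr = np.array(ids)
    orders = []
    for _ in range(scheme.replicates):
        remaining = np.ones(len(ids), dtype=bool)
        order: list[int] = []
        while remaining.any():
            avail = np.flatnonzero(remaining)
            centre = avail[rng.integers(len(avail))]
            d = np.hypot(mid[avail, 0] - mid[centre, 0], mid[avail, 1] - mid[centre, 1])
            take = avail[np.argsort(d, kind="stable")[:k]]
            order.extend(ids_arr[take])
            remaining[take] = False
        orders.append(order)
    return orders


def _midpoint(net: MycelialNetwork, e) -> tuple[float, float]:
    (x1, y1), (x2, y2) = net.nodes[e.u].xy, net.nodes[e.v].xy
    return (0.5 * (x1 + x2), 0.5 * (y1 + y2))


def connected_fraction(net: MycelialNetwork, removed: set[int]) -> float:
    """Fraction of measured edge length still in the Root's component.

    Root edges always stay in place; they carry connectivity but no length.
    """
    if net.root_id is None:
        raise ValueError("network has no Root")
    total = sum(e.length for e in net.measured_edges())
    if total <= 0:
        raise ValueError("network has no measured length")
    nodes = sorted(net.nodes)
    idx = {nid: i for i, nid in enumerate(nodes)}
    uf = _LengthUnionFind(len(nodes))
    for e in net.edges.values():
        if e.id in removed:
            continue
        uf.union(idx[e.u], idx[e.v], 0.0 if e.is_root_edge else e.length)
    return uf.component_length(idx[net.root_id]) / total


class _LengthUnionFind:
    """Union-find tracking total edge length per component."""

    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)
        self.length = np.zeros(n)

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, a: int, b: int, edge_length: float) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            self.length[ra] += edge_length
        else:
            self.parent[rb] = ra
            self.length[ra] += self.length[rb] + edge_length

    def component_length(self, i: int) -> float:
        return float(self.length[self.find(i)])


def _trajectory(net: MycelialNetwork, order: list[int]) -> np.ndarray:
    """Connected fraction after removing order[:m], for m = 0..E.

    Computed by replaying removals backwards as insertions into a
    union-find, so the whole trajectory costs one pass.
    """
    nodes = sorted(net.nodes)
    idx = {nid: i for i, nid in enumerate(nodes)}
    total = sum(e.length for e in net.measured_edges())
    uf = _LengthUnionFind(len(nodes))
    for e in net.root_edges():
        uf.union(idx[e.u], idx[e.v], 0.0)
    in_order = set(order)
    for e in net.measured_edges():
        if e.id not in in_order:
            uf.union(idx[e.u], idx[e.v], e.length)
    root = idx[net.root_id]
    frac = np.empty(len(order) + 1)
    for m in range(len(order), 0, -1):
        frac[m] = uf.component_length(root) / total
        e = net.edges[order[m - 1]]
        uf.union(idx[e.u], idx[e.v], e.length)
    frac[0] = uf.component_length(root) / total
    return frac


def robustness(net: MycelialNetwork, scheme: AttackScheme) -> RobustnessResult:
    """Fraction of edges removed when root-connected length first hits <= 50%.

    Stochastic schemes report the mean over ``scheme.replicates`` runs
    (per-replicate values retained); for random_chunk the crossing is
    assessed only after whole bites, matching a grazer removing a patch
    at a time.
    """
    orders = attack_order(net, scheme)
    n_edges = len(orders[0])
    if scheme.name == "random_chunk":
        k = scheme.effective_chunk_k(n_edges)
        checkpoints = list(range(k, n_edges, k)) + [n_edges]
    else:
        checkpoints = list(range(1, n_edges + 1))

    per_rep: list[float] = []
    counts: list[int] = []
    traj_sum = np.zeros(n_edges + 1)
    for order in orders:
        frac = _trajectory(net, order)
        traj_sum += frac
        crossed = next((m for m in checkpoints if frac[m] <= 0.5), None)
        assert crossed is not None, "full removal must disconnect everything"
        counts.append(crossed)
        per_rep.append(crossed / n_edges)
    return RobustnessResult(
        scheme=scheme.name,
        robustness=float(np.mean(per_rep)),
        per_replicate=per_rep,
        removed_counts=counts,
        trajectory=traj_sum / len(orders),
        n_edges=n_edges,
    )


def robustness_traits(net: MycelialNetwork, seed: int = 0, replicates: int = 100,
                      chunk_k: int | None = None) -> dict[str, float]:
    """All five robustness trait columns for one colony."""
    out: dict[str, float] = {}
    for i, name in enumerate(SCHEME_NAMES):
        scheme = AttackScheme(name, chunk_k=chunk_k, replicates=replicates,
                              seed=seed + i)
        out[SCHEME_COLUMNS[name]] = robustness(net, scheme).robustness
    return out
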