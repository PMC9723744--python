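"""Data model for mycelial networks.

A mycelium is represented as a spatially embedded weighted multigraph.
Nodes are hyphal tips, branch points and anastomosis points; edges are
the hyphal segments (micro scale, µm) or cords (macro scale, mm)
connecting them, each carrying a physical length and a cross-section
width.  The inoculum — the agar plug or wood block the colony grows
from — cannot be resolved into hyphae and is modelled as a single
central "Root" node joined to user-chosen boundary nodes by synthetic
edges; these root edges keep the graph connected but are excluded from
every morphological statistic.

Edge weights used for transport computations are Poiseuille-style
resistances, ``length / (width/2)**alpha`` with ``alpha = 4`` for single
hyphae and ``alpha = 2`` for multi-hyphal cords (a cord widens by adding
hyphae rather than by inflating one tube).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: merge tolerance (physical units) for identifying shared endpoints on load
COORD_MERGE_TOL = 1e-6

#: column schema for edge-list I/O
EDGE_COLUMNS = ("node1", "node2", "length", "width", "x1", "y1", "x2", "y2")


class NetworkValidationError(ValueError):
    """Raised when an edge list or network violates a structural precondition."""


@dataclass
class ResistanceParams:
    """Resistance weighting convention.

    alpha: exponent on the radius; 4 simulates Poiseuille flow through a
        single hyphal tube (micro scale), 2 reflects cords that widen by
        bundling more hyphae (macro scale).
    Radius convention: r = width / 2 (widths are what is measured).
    """

    alpha: float = 4.0

    def __post_init__(self) -> None:
        if self.alpha not in (2, 4, 2.0, 4.0):
            raise ValueError(f"alpha must be 2 or 4, got {self.alpha}")

    @classmethod
    def for_scale(cls, scale_class: str) -> "ResistanceParams":
        if scale_class == "micro":
            return cls(alpha=4.0)
        if scale_class == "macro":
            return cls(alpha=2.0)
        raise ValueError(f"unknown scale_class {scale_class!r}")


def edge_resistance(length: float, width: float, params: ResistanceParams) -> float:
    """Transport resistance of one edge: ``length / (width/2)**alpha``.

    Monotone increasing in length, decreasing in width: long thin hyphae
    resist flow, short wide ones conduct well.
    """
    if length <= 0 or width <= 0:
        raise ValueError(f"length and width must be positive, got {length}, {width}")
    return length / (width / 2.0) ** params.alpha


@dataclass
class MycNode:
    id: int
    xy: tuple[float, float]
    kind: str = "junction"  # one of {root, tip, junction}


@dataclass
class MycEdge:
    id: int
    u: int
    v: int
    length: float
    width: float
    is_root_edge: bool = False
    polyline: list[tuple[float, float]] | None = None

    def volume(self) -> float:
        """Cylindrical volume pi * (width/2)^2 * length."""
        return math.pi * (self.width / 2.0) ** 2 * self.length


class MycelialNetwork:
    """Spatially embedded weighted multigraph with a designated Root.

    Parallel edges are permitted (two hyphae can join the same node
    pair); self-loops are dropped with a warning.  ``scale_class``
    selects the resistance exponent (micro -> 4, macro -> 2).
    """

    def __init__(self, scale_class: str = "micro", pixel_size: float | None = None,
                 metadata: dict | None = None) -> None:
        if scale_class not in ("micro", "macro"):
            raise ValueError(f"scale_class must be 'micro' or 'macro', got {scale_class!r}")
        self.scale_class = scale_class
        self.pixel_size = pixel_size
        self.metadata: dict = dict(metadata or {})
        self.nodes: dict[int, MycNode] = {}
        self.edges: dict[int, MycEdge] = {}
        self.root_id: int | None = None
        self._next_node = 0
        self._next_edge = 0

    # ------------------------------------------------------------------ build
    def add_node(self, xy: Sequence[float], kind: str = "junction",
                 node_id: int | None = None) -> int:
        if node_id is None:
            node_id = self._next_node
        if node_id in self.nodes:
            raise ValueError(f"node id {node_id} already present")
        self.nodes[node_id] = MycNode(node_id, (float(xy[0]), float(xy[1])), kind)
        self._next_node = max(self._next_node, node_id + 1)
        return node_id

    def add_edge(self, u: int, v: int, length: float, width: float,
                 is_root_edge: bool = False,
                 polyline: list[tuple[float, float]] | None = None,
                 edge_id: int | None = None) -> int | None:
        if u not in self.nodes or v not in self.nodes:
            raise NetworkValidationError(f"edge endpoints ({u}, {v}) must exist")
        if u == v:
            logger.warning("dropping self-loop at node %d", u)
            return None
        if length <= 0 or width <= 0:
            raise NetworkValidationError(
                f"edge ({u}, {v}) needs positive length and width, got {length}, {width}")
        if edge_id is None:
            edge_id = self._next_edge
        if edge_id in self.edges:
            raise ValueError(f"edge id {edge_id} already present")
        self.edges[edge_id] = MycEdge(edge_id, u, v, float(length), float(width),
                                      is_root_edge, polyline)
        self._next_edge = max(self._next_edge, edge_id + 1)
        return edge_id

    def remove_edge(self, edge_id: int) -> None:
        del self.edges[edge_id]

    # ------------------------------------------------------------ inspection
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def measured_edges(self) -> Iterator[MycEdge]:
        """Edges measured from the image — root edges excluded."""
        return (e for e in self.edges.values() if not e.is_root_edge)

    def root_edges(self) -> Iterator[MycEdge]:
        return (e for e in self.edges.values() if e.is_root_edge)

    def measured_degree(self, node_id: int) -> int:
        return sum(1 for e in self.measured_edges() if node_id in (e.u, e.v))

    def degree(self, node_id: int) -> int:
        return sum(1 for e in self.edges.values() if node_id in (e.u, e.v))

    def incident_edges(self, node_id: int, measured_only: bool = True) -> list[MycEdge]:
        pool = self.measured_edges() if measured_only else self.edges.values()
        return [e for e in pool if node_id in (e.u, e.v)]

    def tip_nodes(self) -> list[int]:
        """Nodes of measured degree 1 (root-edge attachments do not count)."""
        return [nid for nid in self.nodes
                if nid != self.root_id and self.measured_degree(nid) == 1]

    def classify_nodes(self) -> None:
        """Refresh node kinds from current topology."""
        for nid, node in self.nodes.items():
            if nid == self.root_id:
                node.kind = "root"
            elif self.measured_degree(nid) == 1:
                node.kind = "tip"
            else:
                node.kind = "junction"

    def resistance_params(self) -> ResistanceParams:
        return ResistanceParams.for_scale(self.scale_class)

    def edge_resistances(self) -> dict[int, float]:
        p = self.resistance_params()
        return {eid: edge_resistance(e.length, e.width, p) for eid, e in self.edges.items()}

    # ------------------------------------------------------------ conversion
    def to_multigraph(self) -> nx.MultiGraph:
        """networkx view with length/width/resistance/is_root_edge edge data."""
        g = nx.MultiGraph()
        for nid, node in self.nodes.items():
            g.add_node(nid, x=node.xy[0], y=node.xy[1], kind=node.kind)
        p = self.resistance_params()
        for eid, e in self.edges.items():
            g.add_edge(e.u, e.v, key=eid, length=e.length, width=e.width,
                       resistance=edge_resistance(e.length, e.width, p),
                       is_root_edge=e.is_root_edge)
        return g

    def is_connected(self) -> bool:
        if not self.nodes:
            return True
        return nx.is_connected(self.to_multigraph())

    def copy(self) -> "MycelialNetwork":
        net = MycelialNetwork(self.scale_class, self.pixel_size, dict(self.metadata))
        net.nodes = {nid: replace(n) for nid, n in self.nodes.items()}
        net.edges = {eid: replace(e, polyline=None if e.polyline is None else list(e.polyline))
                     for eid, e in self.edges.items()}
        net.root_id = self.root_id
        net._next_node = self._next_node
        net._next_edge = self._next_edge
        return net

    def total_length(self, measured_only: bool = True) -> float:
        pool = self.measured_edges() if measured_only else self.edges.values()
        return sum(e.length for e in pool)

    def max_measured_width(self) -> float:
        widths = [e.width for e in self.measured_edges()]
        if not widths:
            raise NetworkValidationError("network has no measured edges")
        return max(widths)

    def validate(self) -> None:
        """Check structural invariants; raise NetworkValidationError on failure."""
        for e in self.edges.values():
            if e.u not in self.nodes or e.v not in self.nodes:
                raise NetworkValidationError(f"edge {e.id} references missing node")
            if e.length <= 0 or e.width <= 0:
                raise NetworkValidationError(f"edge {e.id} has nonpositive length/width")
        if self.root_id is not None and self.root_id not in self.nodes:
            raise NetworkValidationError("root_id references a missing node")
        n_roots = sum(1 for n in self.nodes.values() if n.kind == "root")
        if n_roots > 1:
            raise NetworkValidationError(f"{n_roots} root nodes; at most one allowed")


# ---------------------------------------------------------------------- I/O

def _merge_coordinates(points: np.ndarray, tol: float) -> np.ndarray:
    """Assign a cluster label to each 2D point; points within `tol` share a label."""
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    pairs = tree.query_pairs(r=tol, output_type="ndarray")
    # union-find over near-coincident points
    parent = np.arange(len(points))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    return np.array([find(i) for i in range(len(points))])


def load_network(path: str | Path, scale_class: str = "micro",
                 pixel_size: float | None = None,
                 columns: dict[str, str] | None = None,
                 merge_tol: float = COORD_MERGE_TOL) -> MycelialNetwork:
    """Load a mycelial network from an edge-list CSV/XLSX file.

    The file must contain columns node1, node2, length, width, x1, y1,
    x2, y2 (header names remappable through ``columns``); an optional
    boolean ``is_root_edge`` column restores a previously attached Root.
    Endpoint coordinates within ``merge_tol`` are merged into one node.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(path)
        else:
            df = pd.read_csv(path, comment="#")
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read edge list {path}: {exc}") from exc

    colmap = {c: c for c in EDGE_COLUMNS}
    if columns:
        colmap.update(columns)
    missing = [c for c in EDGE_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise NetworkValidationError(f"edge list {path} lacks columns: {missing}")

    lengths = pd.to_numeric(df[colmap["length"]], errors="coerce")
    widths = pd.to_numeric(df[colmap["width"]], errors="coerce")
    for name, series in (("length", lengths), ("width", widths)):
        bad = series.isna() | (series <= 0)
        if bad.any():
            rows = df.index[bad].tolist()
            raise NetworkValidationError(
                f"edge list {path}: missing/nonpositive {name} in rows {rows}")

    pts = np.concatenate([
        df[[colmap["x1"], colmap["y1"]]].to_numpy(float),
        df[[colmap["x2"], colmap["y2"]]].to_numpy(float),
    ])
    labels = _merge_coordinates(pts, merge_tol)

    net = MycelialNetwork(scale_class, pixel_size)
    label_to_node: dict[int, int] = {}
    n_rows = len(df)
    root_flags = (df["is_root_edge"].astype(bool).to_numpy()
                  if "is_root_edge" in df.columns else np.zeros(n_rows, bool))
    kind_lookup: dict[int, str] = {}
    if "kind1" in df.columns and "kind2" in df.columns:
        for i in range(n_rows):
            kind_lookup[labels[i]] = str(df["kind1"].iloc[i])
            kind_lookup[labels[n_rows + i]] = str(df["kind2"].iloc[i])

    for i in range(n_rows):
        ends = []
        for j in (i, n_rows + i):
            lab = labels[j]
            if lab not in label_to_node:
                label_to_node[lab] = net.add_node(pts[j])
            ends.append(label_to_node[lab])
        net.add_edge(ends[0], ends[1], float(lengths.iloc[i]), float(widths.iloc[i]),
                     is_root_edge=bool(root_flags[i]))

    # restore the Root if the file carried root-edge flags or node kinds
    root_label = next((lab for lab, k in kind_lookup.items() if k == "root"), None)
    if root_label is not None and root_label in label_to_node:
        net.root_id = label_to_node[root_label]
    elif root_flags.any():
        counts: dict[int, int] = {}
        for e in net.root_edges():
            counts[e.u] = counts.get(e.u, 0) + 1
            counts[e.v] = counts.get(e.v, 0) + 1
        net.root_id = max(counts, key=counts.get)
    net.classify_nodes()
    return net


def attach_root(net: MycelialNetwork, root_position: Sequence[float],
                boundary_nodes: Iterable[int]) -> MycelialNetwork:
    """Attach the inoculum Root node.

    Adds one node at ``root_position`` and one synthetic edge per
    boundary node, with length the Euclidean root-to-node distance and
    width the maximum measured edge width, making the unresolvable
    inoculum a strong, non-limiting connection.  Root edges are flagged
    and never enter edge statistics.
    Mutates and returns ``net``.
    """
    boundary = list(boundary_nodes)
    if not boundary:
        raise NetworkValidationError("attach_root needs at least one boundary node")
    if net.root_id is not None:
        raise NetworkValidationError("network already has a Root (single-root invariant)")
    width = net.max_measured_width()
    rx, ry = float(root_position[0]), float(root_position[1])
    root_id = net.add_node((rx, ry), kind="root")
    net.root_id = root_id
    for nid in boundary:
        if nid not in net.nodes:
            raise NetworkValidationError(f"boundary node {nid} not in network")
        nx_, ny_ = net.nodes[nid].xy
        dist = math.hypot(nx_ - rx, ny_ - ry)
        if dist <= 0:
            dist = COORD_MERGE_TOL  # boundary node sitting on the root position
        net.add_edge(root_id, nid, dist, width, is_root_edge=True)
    g = net.to_multigraph()
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        logger.warning("network still disconnected after root attachment; components: %s",
                       [len(c) for c in comps])
    net.classify_nodes()
    return net


def write_network(net: MycelialNetwork, path: str | Path, format: str | None = None) -> Path:
    """Write a network as edge-list CSV/XLSX or GraphML.

    The edge-list formats round-trip losslessly through
    :func:`load_network` up to node id relabelling.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".xlsx": "xlsx", ".graphml": "graphml"}.get(
            path.suffix.lower(), "")
    if format not in ("csv", "xlsx", "graphml"):
        raise ValueError(f"unsupported format {format!r}")

    if format == "graphml":
        g = net.to_multigraph()
        g.graph["scale_class"] = net.scale_class
        nx.write_graphml(g, path)
        return path

    rows = []
    for e in sorted(net.edges.values(), key=lambda e: e.id):
        nu, nv = net.nodes[e.u], net.nodes[e.v]
        rows.append({
            "node1": e.u, "node2": e.v, "length": e.length, "width": e.width,
            "x1": nu.xy[0], "y1": nu.xy[1], "x2": nv.xy[0], "y2": nv.xy[1],
            "is_root_edge": e.is_root_edge, "kind1": nu.kind, "kind2": nv.kind,
        })
    df = pd.DataFrame(rows, columns=["node1", "node2", "length", "width",
                                     "x1", "y1", "x2", "y2", "is_root_edge",
                                     "kind1", "kind2"])
    if format == "csv":
        df.to_csv(path, index=False)
    else:
        df.to_excel(path, index=False)
    return path
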