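"""Morphological traits of a mycelium (traits 1–5).

Five summary traits computed from the measured (non-root) edges:
mean hyphal length, mean tip-edge width, mean main-edge width, mean
branching angle, and mycelial length density (total hyphal length per
unit colony area, the colony area being the convex hull of the measured
node positions).  Tip edges connect to a hyphal tip (degree-1 node);
main edges join two internal nodes — the Root counts as internal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .core import MycelialNetwork

import pandas as pd


@dataclass
class MorphTraits:
    mean_edge_length: float
    mean_tip_width: float | None
    mean_main_width: float | None
    mean_branch_angle: float | None
    length_density: float

    def as_dict(self) -> dict[str, float | None]:
        return {
            "mean_edge_length": self.mean_edge_length,
            "mean_tip_width": self.mean_tip_width,
            "mean_main_width": self.mean_main_width,
            "mean_branch_angle": self.mean_branch_angle,
            "length_density": self.length_density,
        }


def _measured_coords(net: MycelialNetwork) -> np.ndarray:
    """Coordinates of nodes touched by measured edges (root geometry excluded)."""
    ids: set[int] = set()
    for e in net.measured_edges():
        ids.add(e.u)
        ids.add(e.v)
    ids.discard(net.root_id)
    # the root may coincide with a measured node; keep it if it carries measured edges
    if net.root_id is not None and net.measured_degree(net.root_id) > 0:
        ids.add(net.root_id)
    return np.array([net.nodes[i].xy for i in sorted(ids)], dtype=float)


def mycelial_area(net: MycelialNetwork) -> float:
    """Convex-hull area of the measured node coordinates (the colony outline)."""
    pts = _measured_coords(net)
    if len(pts) < 3:
        raise ValueError("mycelial_area needs at least 3 measured nodes")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError("mycelial_area undefined for collinear node sets") from exc
    return float(hull.volume)  # 2D "volume" is the area


def _tip_ids(net: MycelialNetwork) -> set[int]:
    return set(net.tip_nodes())


def morphological_traits(net: MycelialNetwork) -> MorphTraits:
    """Traits 1–5; root edges excluded everywhere.

    mean_tip_width / mean_main_width are None (flagged missing, never
    zero) when no edge of the corresponding class exists.
    """
    edges = list(net.measured_edges())
    if not edges:
        raise ValueError("network has no measured edges")
    tips = _tip_ids(net)
    lengths = np.array([e.length for e in edges])
    tip_w = [e.width for e in edges if e.u in tips or e.v in tips]
    main_w = [e.width for e in edges if e.u not in tips and e.v not in tips]
    angles = branching_angles(net)
    return MorphTraits(
        mean_edge_length=float(lengths.mean()),
        mean_tip_width=float(np.mean(tip_w)) if tip_w else None,
        mean_main_width=float(np.mean(main_w)) if main_w else None,
        mean_branch_angle=float(np.mean(angles)) if angles else None,
        length_density=float(lengths.sum() / mycelial_area(net)),
    )


def _edge_direction(net: MycelialNetwork, e, at: int) -> np.ndarray | None:
    """Unit chord from junction `at` toward the edge's first waypoint."""
    if e.polyline:
        pts = e.polyline
        if math.dist(pts[0], net.nodes[at].xy) > math.dist(pts[-1], net.nodes[at].xy):
            pts = pts[::-1]
        target = pts[1]
    else:
        other = e.v if e.u == at else e.u
        target = net.nodes[other].xy
    v = np.asarray(target, float) - np.asarray(net.nodes[at].xy, float)
    n = np.hypot(*v)
    return None if n < 1e-12 else v / n


def branching_angles(net: MycelialNetwork) -> list[float]:
    """Daughter–daughter angles at junctions, in degrees in (0, 180].

    At each junction the incident edge whose far endpoint is
    resistance-closest to the Root is taken as the parent (root-proximal
    growth direction); the branching angle is the angle between the two
    non-parent (daughter) edges.  Junctions of degree >= 4 contribute
    their minimum pairwise daughter angle.  Without a Root the parent is
    undefined, so the minimum pairwise angle over all incident edges is
    used.
    """
    root_dist: dict[int, float] | None = None
    if net.root_id is not None:
        from .network_traits import shortest_path_distances

        root_dist = shortest_path_distances(net, [net.root_id])[net.root_id]

    out: list[float] = []
    for nid in net.nodes:
        if nid == net.root_id:
            continue
        inc = net.incident_edges(nid, measured_only=True)
        if len(inc) < 3:
            continue
        dirs = []
        for e in inc:
            d = _edge_direction(net, e, nid)
            if d is not None:
                far = e.v if e.u == nid else e.u
                dirs.append((e, d, far))
        if len(dirs) < 3:
            continue
        if root_dist is not None:
            parent_idx = min(range(len(dirs)),
                             key=lambda i: (root_dist.get(dirs[i][2], math.inf), dirs[i][0].id))
            daughters = [d for i, (_, d, _) in enumerate(dirs) if i != parent_idx]
        else:
            daughters = [d for _, d, _ in dirs]
        out.append(_min_pairwise_angle(daughters))
    return out


def _min_pairwise_angle(dirs: list[np.ndarray]) -> float:
    best = 180.0
    for i in range(len(dirs)):
        for j in range(i + 1, len(dirs)):
            c = float(np.clip(np.dot(dirs[i], dirs[j]), -1.0, 1.0))
            best = min(best, math.degrees(math.acos(c)))
    return best


def edge_distributions(net: MycelialNetwork) -> pd.DataFrame:
    """Tidy per-edge table (length, width, incident kind) for distribution export.

    incident_kind is 'tip' for edges touching a hyphal tip, else 'main'.
    Root edges are excluded.
    """
    tips = _tip_ids(net)
    rows = [{
        "edge_id": e.id,
        "length": e.length,
        "width": e.width,
        "incident_kind": "tip" if (e.u in tips or e.v in tips) else "main",
    } for e in net.measured_edges()]
    return pd.DataFrame(rows, columns=["edge_id", "length", "width", "incident_kind"])
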