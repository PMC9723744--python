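"""Seeded generator of foraging mycelia and a micrograph-style renderer.

The generator emulates a colony growing out of a central inoculum into a
nutrient-poor arena: hyphal tips advance stepwise with persistent
headings plus Gaussian angular noise, branch laterally with a per-step
probability, and fuse with (anastomose onto) an existing hypha when they
come within a capture radius.  Varying branching and fusion rates spans
the classic foraging gradient: sparse, long-stepping, rarely fusing
"guerrilla" explorers through to densely branched, heavily cross-linked
"phalanx" exploiters.  Crossings always create nodes, so generated
networks are planar, as 2D image extractions are.

Step lengths are log-normal; widths are log-normal with a small log-sd
(~10% coefficient of variation), tip edges thinner than main edges,
mirroring the near-log-normal hyphal dimension distributions observed in
real colonies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .core import MycelialNetwork, attach_root

logger = logging.getLogger(__name__)


@dataclass
class SynthParams:
    """Growth-model parameters (micro-scale units: µm, degrees).

    step_length_mu is the median step length (log-normal scale
    parameter); step_length_sigma the log-sd.  branch_prob is the
    per-tip per-step probability of spawning a lateral daughter.
    fuse_radius / fuse_prob control anastomosis: a tip stepping within
    fuse_radius of an existing hypha fuses with probability fuse_prob
    (otherwise it halts, so fuse_prob = 0 yields a tree).  width_tip /
    width_main are median widths for tip-incident vs internal edges.
    """

    n_steps: int = 50
    step_length_mu: float = 38.0
    step_length_sigma: float = 0.30
    branch_prob: float = 0.30
    branch_angle_mu: float = 75.0
    branch_angle_sigma: float = 12.0
    heading_noise_sd: float = 10.0
    fuse_radius: float = 10.0
    fuse_prob: float = 0.3
    width_tip: float = 2.7
    width_main: float = 4.5
    arena_radius: float = 450.0
    n_initial_tips: int = 8
    inoculum_radius: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1 (empty network otherwise)")
        for p in (self.branch_prob, self.fuse_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probabilities must lie in [0, 1], got {p}")
        for name in ("step_length_mu", "step_length_sigma", "fuse_radius",
                     "width_tip", "width_main", "arena_radius", "inoculum_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


_PRESETS = {
    # sparse explorer: long thick hyphae, little branching, no fusion
    "guerrilla": dict(branch_prob=0.22, fuse_prob=0.0, fuse_radius=8.0,
                      step_length_mu=50.0, heading_noise_sd=7.0,
                      width_tip=3.5, width_main=6.0, n_initial_tips=10),
    # dense exploiter: short thin hyphae, frequent branching and anastomosis
    "phalanx": dict(branch_prob=0.50, fuse_prob=0.65, fuse_radius=12.0,
                    step_length_mu=26.0, heading_noise_sd=14.0,
                    width_tip=2.0, width_main=3.2),
    "intermediate": dict(branch_prob=0.30, fuse_prob=0.30, fuse_radius=10.0,
                         step_length_mu=38.0, heading_noise_sd=10.0,
                         width_tip=2.7, width_main=4.5),
}


def preset_params(phenotype: str, seed: int = 0, **overrides) -> SynthParams:
    """Parameter presets spanning the guerrilla–phalanx foraging gradient."""
    if phenotype not in _PRESETS:
        raise ValueError(f"unknown phenotype {phenotype!r}; choose from {sorted(_PRESETS)}")
    kw = dict(_PRESETS[phenotype])
    kw.update(overrides)
    return SynthParams(seed=seed, **kw)


class _SegmentStore:
    """Growable numpy store of edge segments for proximity/crossing queries."""

    def __init__(self, capacity: int = 256) -> None:
        self.a = np.empty((capacity, 2))
        self.b = np.empty((capacity, 2))
        self.edge_id = np.empty(capacity, dtype=np.int64)
        self.n = 0

    def _grow(self) -> None:
        cap = len(self.edge_id) * 2
        self.a = np.resize(self.a, (cap, 2))
        self.b = np.resize(self.b, (cap, 2))
        self.edge_id = np.resize(self.edge_id, cap)

    def add(self, a, b, edge_id: int) -> int:
        if self.n == len(self.edge_id):
            self._grow()
        i = self.n
        self.a[i], self.b[i], self.edge_id[i] = a, b, edge_id
        self.n += 1
        return i

    def set(self, i: int, a, b, edge_id: int) -> None:
        self.a[i], self.b[i], self.edge_id[i] = a, b, edge_id

    def nearest(self, p: np.ndarray, exclude: set[int]):
        """(distance, store index, closest point) of the segment nearest to p."""
        n = self.n
        if n == 0:
            return math.inf, -1, None
        a, b = self.a[:n], self.b[:n]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.einsum("ij,ij->i", p - a, ab) / np.maximum(denom, 1e-30)
        t = np.clip(t, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = np.einsum("ij,ij->i", p - proj, p - proj)
        if exclude:
            mask = np.isin(self.edge_id[:n], list(exclude))
            d2 = np.where(mask, np.inf, d2)
        i = int(np.argmin(d2))
        return math.sqrt(d2[i]), i, proj[i]

    def first_crossing(self, p: np.ndarray, q: np.ndarray, exclude: set[int]):
        """Earliest intersection of segment p→q with stored segments, or None."""
        n = self.n
        if n == 0:
            return None
        a, b = self.a[:n], self.b[:n]
        r = q - p
        s = b - a
        denom = r[0] * s[:, 1] - r[1] * s[:, 0]
        qp = a - p
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (qp[:, 0] * s[:, 1] - qp[:, 1] * s[:, 0]) / denom
            u = (qp[:, 0] * r[1] - qp[:, 1] * r[0]) / denom
        hit = (np.abs(denom) > 1e-12) & (t > 1e-9) & (t < 1 - 1e-9) & (u > 1e-9) & (u < 1 - 1e-9)
        if exclude:
            hit &= ~np.isin(self.edge_id[:n], list(exclude))
        if not hit.any():
            return None
        idx = np.where(hit)[0]
        j = idx[np.argmin(t[idx])]
        return float(t[j]), int(j), p + t[j] * r


class _Tip:
    __slots__ = ("node", "pos", "heading", "alive")

    def __init__(self, node: int, pos: np.ndarray, heading: float) -> None:
        self.node = node
        self.pos = pos
        self.heading = heading
        self.alive = True


def grow_network(params: SynthParams) -> MycelialNetwork:
    """Grow one synthetic colony; identical params + seed give identical output.

    Returns a root-attached, validated :class:`MycelialNetwork` (micro
    scale).  Degree-2 chain nodes left by un-branched elongation are
    dissolved so interior nodes are genuine junctions.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    net = MycelialNetwork("micro", metadata={"generator": "myconet.synthetic",
                                             "seed": params.seed})
    store = _SegmentStore()
    seg_of_edge: dict[int, int] = {}  # edge id -> store slot (edges are single segments here)

    # initial tips on the inoculum rim, headings radially outward with jitter
    tips: list[_Tip] = []
    boundary: list[int] = []
    for k in range(params.n_initial_tips):
        theta = 2 * math.pi * k / params.n_initial_tips + rng.normal(0, 0.1)
        pos = params.inoculum_radius * np.array([math.cos(theta), math.sin(theta)])
        nid = net.add_node(pos)
        boundary.append(nid)
        tips.append(_Tip(nid, pos, theta))

    def add_seg_edge(u: int, v: int, pu: np.ndarray, pv: np.ndarray) -> int | None:
        length = float(np.hypot(*(pv - pu)))
        eid = net.add_edge(u, v, max(length, 1e-9), 1.0)  # widths assigned later
        if eid is not None:
            seg_of_edge[eid] = store.add(pu, pv, eid)
        return eid

    # node separations below a hyphal width are unresolvable in an image;
    # snap capture points onto an existing endpoint inside this tolerance
    snap_tol = params.width_main

    def split_edge(store_idx: int, point: np.ndarray) -> int:
        """Split the stored segment-edge at `point`; return the junction node id."""
        eid = int(store.edge_id[store_idx])
        e = net.edges[eid]
        pa, pb = store.a[store_idx].copy(), store.b[store_idx].copy()
        if float(np.hypot(*(point - pa))) < snap_tol:
            return e.u
        if float(np.hypot(*(point - pb))) < snap_tol:
            return e.v
        nid = net.add_node(point)
        net.remove_edge(eid)
        del seg_of_edge[eid]
        # reuse the store slot for the first half
        l1 = max(float(np.hypot(*(point - pa))), 1e-9)
        l2 = max(float(np.hypot(*(pb - point))), 1e-9)
        e1 = net.add_edge(e.u, nid, l1, 1.0)
        e2 = net.add_edge(nid, e.v, l2, 1.0)
        if e1 is not None:
            store.set(store_idx, pa, point, e1)
            seg_of_edge[e1] = store_idx
        if e2 is not None:
            seg_of_edge[e2] = store.add(point, pb, e2)
        return nid

    noise_rad = math.radians(params.heading_noise_sd)
    log_mu = math.log(params.step_length_mu)

    for _ in range(params.n_steps):
        for tip in list(tips):
            if not tip.alive:
                continue
            tip.heading += rng.normal(0, noise_rad)
            length = rng.lognormal(log_mu, params.step_length_sigma)
            direction = np.array([math.cos(tip.heading), math.sin(tip.heading)])
            new_pos = tip.pos + length * direction

            if np.hypot(*new_pos) > params.arena_radius:
                tip.alive = False  # halted at the arena boundary; stays a tip
                continue

            exclude = {e.id for e in net.incident_edges(tip.node, measured_only=False)}
            crossing = store.first_crossing(tip.pos, new_pos, exclude)
            dist, near_idx, near_pt = store.nearest(new_pos, exclude)

            if crossing is not None or dist < params.fuse_radius:
                if rng.random() < params.fuse_prob:
                    # anastomosis: capture onto the nearest point / crossing point
                    if crossing is not None:
                        _, idx, point = crossing
                    else:
                        idx, point = near_idx, near_pt
                    point = np.asarray(point)
                    fuse_node = split_edge(idx, point)
                    if fuse_node != tip.node and np.hypot(*(point - tip.pos)) > 1e-6:
                        add_seg_edge(tip.node, fuse_node,
                                     tip.pos, np.asarray(net.nodes[fuse_node].xy))
                else:
                    # dense neighbourhood, no fusion: the tip halts short
                    if crossing is not None:
                        t_hit = crossing[0]
                        stop = tip.pos + 0.5 * t_hit * (new_pos - tip.pos)
                        if np.hypot(*(stop - tip.pos)) > snap_tol:
                            nid = net.add_node(stop)
                            add_seg_edge(tip.node, nid, tip.pos, stop)
                tip.alive = False
                continue

            nid = net.add_node(new_pos)
            add_seg_edge(tip.node, nid, tip.pos, new_pos)
            tip.node, tip.pos = nid, new_pos

            if rng.random() < params.branch_prob:
                angle = math.radians(rng.normal(params.branch_angle_mu,
                                                params.branch_angle_sigma))
                side = 1.0 if rng.random() < 0.5 else -1.0
                tips.append(_Tip(nid, new_pos, tip.heading + side * angle))

    dissolve_degree2(net)
    _assign_widths(net, params, rng)
    boundary = [b for b in boundary if b in net.nodes]
    attach_root(net, (0.0, 0.0), boundary)
    net.validate()
    return net


def dissolve_degree2(net: MycelialNetwork, protect: set[int] | None = None) -> None:
    """Merge chains through degree-2 nodes into single polyline edges.

    Each merge concatenates the two incident edges: lengths sum, widths
    are length-weighted averaged, polylines concatenated.  Nodes in
    `protect`, the root, and nodes touching root edges are kept.
    """
    protect = set(protect or ())
    if net.root_id is not None:
        protect.add(net.root_id)
    for e in net.root_edges():
        protect.update((e.u, e.v))

    changed = True
    while changed:
        changed = False
        for nid in list(net.nodes):
            if nid in protect or nid not in net.nodes:
                continue
            inc = net.incident_edges(nid, measured_only=False)
            if len(inc) != 2:
                continue
            e1, e2 = inc
            if e1.id == e2.id:
                continue
            u = e1.u if e1.v == nid else e1.v
            v = e2.u if e2.v == nid else e2.v
            length = e1.length + e2.length
            width = (e1.width * e1.length + e2.width * e2.length) / length
            poly = _join_polylines(net, e1, e2, nid, u, v)
            net.remove_edge(e1.id)
            net.remove_edge(e2.id)
            del net.nodes[nid]
            if u != v:
                net.add_edge(u, v, length, width, polyline=poly)
            else:
                logger.warning("dissolving node %d produced a self-loop; dropped", nid)
            changed = True


def _edge_polyline(net: MycelialNetwork, e, start: int) -> list[tuple[float, float]]:
    pts = e.polyline
    if pts is None:
        pts = [net.nodes[e.u].xy, net.nodes[e.v].xy]
    if math.dist(pts[0], net.nodes[start].xy) > math.dist(pts[-1], net.nodes[start].xy):
        pts = pts[::-1]
    return list(pts)


def _join_polylines(net, e1, e2, via: int, u: int, v: int) -> list[tuple[float, float]]:
    p1 = _edge_polyline(net, e1, u)
    p2 = _edge_polyline(net, e2, via)
    return p1 + p2[1:]


def _assign_widths(net: MycelialNetwork, params: SynthParams, rng: np.random.Generator) -> None:
    """Tip-incident edges get thin widths, interior edges thick ones.

    Log-normal with log-sd 0.1 (≈10% CV) around the configured medians.
    """
    deg = {nid: net.measured_degree(nid) for nid in net.nodes}
    for e in net.measured_edges():
        tip_incident = deg[e.u] == 1 or deg[e.v] == 1
        mu = params.width_tip if tip_incident else params.width_main
        e.width = float(rng.lognormal(math.log(mu), 0.1))


# ------------------------------------------------------------------ renderer

@dataclass
class RenderedImage:
    """A rendered micrograph plus the geometry needed to score extraction."""

    image: np.ndarray           # uint8 grayscale, foreground bright unless inverted
    origin: tuple[float, float]  # physical coordinates of pixel (row 0, col 0) centre
    pixel_size: float
    net: MycelialNetwork        # ground truth


def render_image(net: MycelialNetwork, pixel_size: float, blur_sigma: float = 1.0,
                 noise_sd: float = 0.0, invert: bool = False,
                 seed: int | None = 0, margin: float | None = None) -> RenderedImage:
    """Rasterize the measured edges as anti-aliased thick lines.

    Each edge (or each segment of its polyline) is drawn with thickness
    ``width / pixel_size`` pixels; Gaussian blur and additive Gaussian
    noise emulate optics and sensor noise.  Root edges are synthetic and
    are not drawn.  Raises if the widest edge would be under one pixel.
    """
    from scipy.ndimage import gaussian_filter

    edges = list(net.measured_edges())
    xs = [n.xy[0] for n in net.nodes.values()] or [0.0]
    ys = [n.xy[1] for n in net.nodes.values()] or [0.0]
    if edges and max(e.width for e in edges) / pixel_size < 1.0:
        raise ValueError("pixel_size too coarse: max edge width below one pixel")
    if margin is None:
        margin = 10 * pixel_size + max((e.width for e in edges), default=0.0)
    x0, y0 = min(xs) - margin, min(ys) - margin
    w = int(math.ceil((max(xs) - x0 + margin) / pixel_size)) + 1
    h = int(math.ceil((max(ys) - y0 + margin) / pixel_size)) + 1
    canvas = np.zeros((h, w), dtype=float)

    for e in edges:
        pts = e.polyline or [net.nodes[e.u].xy, net.nodes[e.v].xy]
        half = e.width / 2.0 / pixel_size
        for (ax, ay), (bx, by) in zip(pts[:-1], pts[1:]):
            pa = np.array([(ax - x0) / pixel_size, (ay - y0) / pixel_size])
            pb = np.array([(bx - x0) / pixel_size, (by - y0) / pixel_size])
            _stamp_segment(canvas, pa, pb, half)

    if blur_sigma > 0:
        canvas = gaussian_filter(canvas, blur_sigma)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        canvas = canvas + rng.normal(0, noise_sd, canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    if invert:
        canvas = 1.0 - canvas
    img = np.round(canvas * 255).astype(np.uint8)
    return RenderedImage(img, (x0, y0), pixel_size, net)


def _stamp_segment(canvas: np.ndarray, pa: np.ndarray, pb: np.ndarray, half_px: float) -> None:
    """Max-composite an anti-aliased thick segment onto the canvas."""
    h, w = canvas.shape
    pad = half_px + 2.0
    cmin = max(int(math.floor(min(pa[0], pb[0]) - pad)), 0)
    cmax = min(int(math.ceil(max(pa[0], pb[0]) + pad)), w - 1)
    rmin = max(int(math.floor(min(pa[1], pb[1]) - pad)), 0)
    rmax = min(int(math.ceil(max(pa[1], pb[1]) + pad)), h - 1)
    if cmin > cmax or rmin > rmax:
        return
    cc, rr = np.meshgrid(np.arange(cmin, cmax + 1), np.arange(rmin, rmax + 1))
    p = np.stack([cc, rr], axis=-1).astype(float)
    ab = pb - pa
    denom = float(ab @ ab)
    if denom < 1e-30:
        d = np.hypot(p[..., 0] - pa[0], p[..., 1] - pa[1])
    else:
        t = np.clip(((p - pa) @ ab) / denom, 0.0, 1.0)
        proj = pa + t[..., None] * ab
        d = np.hypot(p[..., 0] - proj[..., 0], p[..., 1] - proj[..., 1])
    val = np.clip(half_px + 0.5 - d, 0.0, 1.0)
    region = canvas[rmin:rmax + 1, cmin:cmax + 1]
    np.maximum(region, val, out=region)


def save_image(rendered: RenderedImage, path) -> None:
    """Write the rendered frame as PNG or TIFF (by extension)."""
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, rendered.image)
    else:
        from PIL import Image

        Image.fromarray(rendered.image).save(path)
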