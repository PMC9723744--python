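"""Extraction of a width-annotated network from a mycelium image.

The stages mirror the standard phenotyping pipeline: background
correction (morphological top-hat), optional curvilinear ridge
enhancement, segmentation, topology-preserving skeletonization,
skeleton-to-graph conversion (tips and junction clusters become nodes,
pixel-traced paths become edges), distance-transform width estimation,
and spur pruning.  Extraction is deterministic.

Crossings and true anastomoses are indistinguishable in a 2D
projection; both become junction nodes.  Image coordinates map to
physical coordinates as ``x = column * pixel_size``,
``y = row * pixel_size``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import sato, threshold_otsu
from skimage.measure import label
from skimage.morphology import disk, skeletonize, white_tophat

from .core import MycelialNetwork, attach_root
from .synthetic import dissolve_degree2

logger = logging.getLogger(__name__)


@dataclass
class ExtractionParams:
    """Tunable extraction settings.

    pixel_size is the physical size of one pixel (µm for micrographs,
    mm-scale for soil mesocosm photographs) and is required for every
    physical quantity downstream.  min_spur_length defaults to
    3 * pixel_size when left as None.
    """

    pixel_size: float = 1.0
    background_radius: int = 20          # px; larger than the widest hypha radius
    enhancement: str = "none"            # {"none", "ridge"}
    ridge_sigmas: tuple[float, ...] = (1.0, 2.0, 3.0)
    threshold_method: str = "otsu"       # {"otsu", "fixed"}
    fixed_threshold: float | None = None
    invert: bool = False                 # set when hyphae are dark on bright field
    min_object_px: int = 30              # despeckle: drop smaller foreground blobs
    min_spur_length: float | None = None
    node_merge_radius: float = 2.0       # px; junction-pixel cluster merge radius

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.background_radius <= 0 or self.node_merge_radius <= 0:
            raise ValueError("radii must be positive")
        if self.enhancement not in ("none", "ridge"):
            raise ValueError(f"unknown enhancement {self.enhancement!r}")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")

    @property
    def spur_length(self) -> float:
        return (3.0 * self.pixel_size if self.min_spur_length is None
                else self.min_spur_length)


def preprocess(image: np.ndarray, params: ExtractionParams) -> np.ndarray:
    """Background-correct, optionally ridge-enhance, and binarize.

    Returns a boolean mask with foreground = hyphae.  The "ridge" mode
    thresholds a multiscale second-derivative (Sato) vesselness response
    and is intensity-independent, at the price of some width distortion;
    the default intensity mode preserves widths on well-corrected images.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 1e-12:
        raise ValueError("constant image: nothing to segment")
    img = (img - lo) / (hi - lo)
    if params.invert:
        img = 1.0 - img

    corrected = white_tophat(img, footprint=disk(params.background_radius))
    signal = (sato(corrected, sigmas=params.ridge_sigmas, black_ridges=False)
              if params.enhancement == "ridge" else corrected)

    if params.threshold_method == "fixed":
        if params.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")
        thr = params.fixed_threshold
    else:
        # Otsu always splits, even pure noise; guard it with a robust
        # background floor (median + 5 sigma via the MAD) so structureless
        # frames yield an almost empty mask
        med = float(np.median(signal))
        mad = float(np.median(np.abs(signal - med)))
        thr = max(threshold_otsu(signal), med + 5.0 * 1.4826 * mad)
    mask = signal > thr
    if params.min_object_px > 1:
        lab, n = ndi.label(mask, structure=np.ones((3, 3)))
        if n:
            sizes = ndi.sum_labels(mask, lab, index=np.arange(1, n + 1))
            keep = np.flatnonzero(sizes >= params.min_object_px) + 1
            mask = np.isin(lab, keep)
    return mask


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to a 1-px-wide skeleton (subset of the mask)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return skeletonize(mask)


_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def skeleton_to_graph(skeleton: np.ndarray, params: ExtractionParams) -> MycelialNetwork:
    """Convert a 1-px skeleton into a network (widths not yet estimated).

    Pixels with one skeleton neighbour become tips; pixels with three or
    more, clustered within node_merge_radius, become junctions (placed
    at the cluster centroid).  Edges are traced pixel-by-pixel between
    nodes; arc length counts diagonal steps as sqrt(2) pixels, times
    pixel_size.  Edges get a provisional unit width.
    """
    skel = np.asarray(skeleton, dtype=bool)
    ps = params.pixel_size
    net = MycelialNetwork("micro", pixel_size=ps)
    if not skel.any():
        return net

    nbr_count = ndi.convolve(skel.astype(np.uint8), np.ones((3, 3), np.uint8),
                             mode="constant") - 1
    nbr_count[~skel] = 0
    junction_px = skel & (nbr_count >= 3)
    tip_px = skel & (nbr_count == 1)

    # cluster junction pixels within the merge radius
    merged = ndi.binary_dilation(junction_px,
                                 structure=disk(max(1, int(round(params.node_merge_radius)))))
    labels = label(merged, connectivity=2)
    labels[~junction_px] = 0

    node_of_px: dict[tuple[int, int], int] = {}
    for lab in range(1, labels.max() + 1):
        rr, cc = np.nonzero(labels == lab)
        if rr.size == 0:
            continue
        cx, cy = float(cc.mean()) * ps, float(rr.mean()) * ps
        nid = net.add_node((cx, cy), kind="junction")
        for r, c in zip(rr, cc):
            node_of_px[(int(r), int(c))] = nid
    for r, c in zip(*np.nonzero(tip_px)):
        key = (int(r), int(c))
        if key not in node_of_px:
            node_of_px[key] = net.add_node((c * ps, r * ps), kind="tip")

    visited_steps: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    used_px: set[tuple[int, int]] = set()

    def neighbours(p):
        r, c = p
        for dr, dc in _NEIGHBOURS:
            q = (r + dr, c + dc)
            if 0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1] and skel[q]:
                yield q

    def trace(start_px, first_px):
        """Follow degree-2 pixels from a node pixel until the next node pixel."""
        path = [start_px, first_px]
        prev, cur = start_px, first_px
        while cur not in node_of_px:
            used_px.add(cur)
            nxt = [q for q in neighbours(cur) if q != prev and
                   (q not in path[-2:])]
            # prefer unvisited continuations; at a skeleton artefact pick stably
            nxt = [q for q in nxt if q not in node_of_px or q != start_px or len(path) > 2]
            if not nxt:
                return path, None
            nxt.sort()
            step = next((q for q in nxt if q in node_of_px), nxt[0])
            path.append(step)
            prev, cur = cur, step
        return path, cur

    for px, nid in list(node_of_px.items()):
        for q in neighbours(px):
            if q in node_of_px and node_of_px[q] == nid:
                continue
            if (px, q) in visited_steps:
                continue
            path, end_px = trace(px, q)
            if end_px is None:
                continue
            visited_steps.add((px, q))
            visited_steps.add((path[-1], path[-2]))
            end_id = node_of_px[end_px]
            if end_id == nid and len(path) <= 3:
                continue  # internal hop within one junction cluster
            arc = sum(math.hypot(a[0] - b[0], a[1] - b[1])
                      for a, b in zip(path[:-1], path[1:])) * ps
            poly = ([net.nodes[nid].xy]
                    + [(c * ps, r * ps) for r, c in path[1:-1]]
                    + [net.nodes[end_id].xy])
            chord = math.dist(net.nodes[nid].xy, net.nodes[end_id].xy)
            net.add_edge(nid, end_id, max(arc, chord, 0.5 * ps), 1.0, polyline=poly)

    leftover = skel & (nbr_count == 2)
    lr, lc = np.nonzero(leftover)
    loop_px = [(int(r), int(c)) for r, c in zip(lr, lc)
               if (int(r), int(c)) not in used_px and (int(r), int(c)) not in node_of_px]
    if loop_px:
        logger.warning("skeleton contains %d pixels in node-free closed loops; "
                       "represented as self-loops and dropped", len(loop_px))
    net.classify_nodes()
    return net


def estimate_widths(net: MycelialNetwork, mask: np.ndarray,
                    pixel_size: float) -> MycelialNetwork:
    """Per-edge width from the Euclidean distance transform of the mask.

    width = (2 * median EDT - 1) * pixel_size sampled along the edge
    polyline (the -1 px corrects for the sample sitting on a pixel
    centre).  Samples falling outside the mask are ignored; an edge with
    no in-mask samples gets a one-pixel floor width with a warning.
    """
    edt = ndi.distance_transform_edt(np.asarray(mask, dtype=bool))
    h, w = edt.shape
    for e in net.measured_edges():
        pts = e.polyline or [net.nodes[e.u].xy, net.nodes[e.v].xy]
        samples = []
        for x, y in _densify(pts, pixel_size):
            r, c = int(round(y / pixel_size)), int(round(x / pixel_size))
            if 0 <= r < h and 0 <= c < w and edt[r, c] > 0:
                samples.append(edt[r, c])
        if samples:
            e.width = max((2.0 * float(np.median(samples)) - 1.0), 1.0) * pixel_size
        else:
            logger.warning("edge %d lies outside the mask; width floored", e.id)
            e.width = pixel_size
    return net


def _densify(pts, step):
    """Points along a polyline at roughly one-pixel spacing."""
    out = [tuple(pts[0])]
    for (ax, ay), (bx, by) in zip(pts[:-1], pts[1:]):
        d = math.hypot(bx - ax, by - ay)
        n = max(1, int(d / step))
        for i in range(1, n + 1):
            t = i / n
            out.append((ax + t * (bx - ax), ay + t * (by - ay)))
    return out


def prune_and_clean(net: MycelialNetwork, params: ExtractionParams) -> MycelialNetwork:
    """Iteratively remove short terminal spurs, then dissolve degree-2 nodes.

    Spurs are skeletonization artefacts: terminal edges shorter than
    min_spur_length.  Dissolution concatenates the pass-through chains
    pruning leaves behind (lengths sum, widths length-weighted).
    """
    changed = True
    while changed:
        changed = False
        for e in list(net.measured_edges()):
            if e.id not in net.edges:
                continue
            deg_u, deg_v = net.measured_degree(e.u), net.measured_degree(e.v)
            if (deg_u == 1 or deg_v == 1) and e.length < params.spur_length:
                # never prune an isolated edge down to nothing
                if deg_u == 1 and deg_v == 1:
                    continue
                tip_end = e.u if deg_u == 1 else e.v
                net.remove_edge(e.id)
                if net.degree(tip_end) == 0 and tip_end != net.root_id:
                    del net.nodes[tip_end]
                changed = True
    dissolve_degree2(net)
    net.classify_nodes()
    return net


def extract_network(image: np.ndarray, params: ExtractionParams,
                    inoculum_center: tuple[float, float] | None = None,
                    inoculum_radius: float | None = None) -> MycelialNetwork:
    """Full image-to-network pipeline.

    If an inoculum disk (physical coordinates/radius) is supplied, the
    unresolvable inoculum region is masked out, the nodes on its rim
    become boundary nodes, and a Root is attached at its centre.
    """
    mask = preprocess(image, params)
    ps = params.pixel_size
    if inoculum_center is not None and inoculum_radius is not None:
        rr, cc = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
        d = np.hypot(cc * ps - inoculum_center[0], rr * ps - inoculum_center[1])
        mask = mask & (d > inoculum_radius)
    skel = skeletonize_mask(mask)
    net = skeleton_to_graph(skel, params)
    if net.n_edges == 0:
        raise ValueError("no network structure found in image")
    estimate_widths(net, mask, ps)
    prune_and_clean(net, params)
    if inoculum_center is not None and inoculum_radius is not None:
        cx, cy = inoculum_center
        boundary = [nid for nid, node in net.nodes.items()
                    if math.hypot(node.xy[0] - cx, node.xy[1] - cy)
                    <= inoculum_radius + 3 * ps and net.measured_degree(nid) >= 1]
        if boundary:
            attach_root(net, inoculum_center, boundary)
        else:
            logger.warning("no nodes found on the inoculum rim; Root not attached")
    net.classify_nodes()
    return net
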