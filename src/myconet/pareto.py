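"""Pareto-front archetype analysis of trait tables.

If phenotypes trade off among a small number of "tasks", theory
predicts that colonies fill a low-dimensional polytope in trait space
whose vertices — the archetypes — are the specialists.  We test this in
the plane of the first two principal components: fit the minimal-area
enclosing k-gon, summarize triangularity as the t-ratio (data hull area
over polygon area, 1 = perfectly polytope-shaped data), and compare the
observed t-ratio with a null in which every trait column is permuted
independently (marginals preserved, correlation structure destroyed).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError


@dataclass
class ArchetypeResult:
    scores: np.ndarray          # (n, 2) ordination scores
    k: int
    polygon: np.ndarray         # (k, 2) vertices, counter-clockwise
    t_ratio: float
    p_random: float | None
    n_randomizations: int | None
    nearest_samples: list[tuple[int, float]]  # per vertex: (sample index, distance)
    seed: int | None = None


def ordinate_2d(Y_std, return_basis: bool = False):
    """First two principal-component scores of a standardized trait matrix."""
    Y = np.asarray(Y_std, dtype=float)
    if Y.shape[0] < 3:
        raise ValueError("ordination needs at least 3 samples")
    Yc = Y - Y.mean(axis=0)
    u, s, vt = np.linalg.svd(Yc, full_matrices=False)
    if len(s) < 2 or s[1] <= 1e-10 * max(s[0], 1.0):
        raise ValueError("trait matrix has rank < 2; no 2D ordination exists")
    # deterministic sign: largest-|loading| coefficient positive per axis
    for j in range(2):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u[:, :2] * s[:2]
    if return_basis:
        return scores, vt[:2].T, Y.mean(axis=0)
    return scores


def _hull_ccw(points: np.ndarray) -> np.ndarray:
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) point set") from exc
    return points[hull.vertices]  # scipy returns them counter-clockwise in 2D


def _poly_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _contains_all(poly: np.ndarray, points: np.ndarray, tol: float) -> bool:
    """All points inside a convex ccw polygon (half-plane test per side)."""
    n = len(poly)
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        cross = (b[0] - a[0]) * (points[:, 1] - a[1]) - (b[1] - a[1]) * (points[:, 0] - a[0])
        if np.any(cross < -tol):
            return False
    return True


def _line_intersection(p1, d1, p2, d2):
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-12:
        return None
    t = ((p2[0] - p1[0]) * d2[1] - (p2[1] - p1[1]) * d2[0]) / denom
    return p1 + t * d1


def _orient_ccw(poly: np.ndarray) -> np.ndarray:
    x, y = poly[:, 0], poly[:, 1]
    signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return poly if signed >= 0 else poly[::-1]


def _min_triangle(points: np.ndarray) -> np.ndarray:
    """Minimal-area enclosing triangle via flush-side search.

    The optimal enclosing triangle has at least one side flush with a
    hull edge and non-flush sides touching the hull at side midpoints;
    we enumerate triangles built from hull-edge flush lines combined
    with midpoint-rule third sides through each hull vertex, and keep
    the smallest candidate that contains the hull.
    """
    hull = _hull_ccw(points)
    h = len(hull)
    if h == 3:
        return hull
    scale = float(np.ptp(points, axis=0).max())
    tol = 1e-9 * max(scale, 1.0)
    hull_area = _poly_area(hull)
    A = hull
    E = np.roll(hull, -1, axis=0) - hull  # flush-line directions

    cands: list[np.ndarray] = []
    # three flush sides
    for i, j, k in itertools.combinations(range(h), 3):
        p1 = _line_intersection(A[i], E[i], A[j], E[j])
        p2 = _line_intersection(A[j], E[j], A[k], E[k])
        p3 = _line_intersection(A[k], E[k], A[i], E[i])
        if p1 is not None and p2 is not None and p3 is not None:
            cands.append(np.array([p1, p2, p3]))
    # two flush sides + midpoint-touching third side (all hull vertices at once)
    for i in range(h):
        for j in range(h):
            if i == j:
                continue
            apex = _line_intersection(A[i], E[i], A[j], E[j])
            if apex is None:
                continue
            m = 0.5 * np.column_stack([E[i], E[j]])
            det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
            if abs(det) < 1e-12:
                continue
            minv = np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det
            t = (hull - apex) @ minv.T          # (h, 2): side parameters per vertex
            e1 = apex + t[:, 0:1] * E[i]
            e2 = apex + t[:, 1:2] * E[j]
            cands.extend(np.stack([np.broadcast_to(apex, e1.shape), e1, e2], axis=1))

    cand = np.asarray(cands)                    # (C, 3, 2)
    finite = np.isfinite(cand).all(axis=(1, 2))
    cand = cand[finite]
    v1 = cand[:, 1] - cand[:, 0]
    v2 = cand[:, 2] - cand[:, 0]
    signed = 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
    areas = np.abs(signed)
    # orient all candidates counter-clockwise for a one-sided half-plane test
    cw = signed < 0
    cand[cw] = cand[cw][:, [0, 2, 1]]
    # an enclosing triangle can never be smaller than the hull; this also
    # rejects degenerate collapsed candidates
    ok = areas >= hull_area * (1 - 1e-9)
    for s in range(3):
        a, b = cand[:, s], cand[:, (s + 1) % 3]
        cross = ((b[:, 0, None] - a[:, 0, None]) * (hull[None, :, 1] - a[:, 1, None])
                 - (b[:, 1, None] - a[:, 1, None]) * (hull[None, :, 0] - a[:, 0, None]))
        ok &= (cross >= -tol).all(axis=1)
    if not ok.any():
        raise ValueError("no valid enclosing triangle found (degenerate input)")
    idx = int(np.argmin(np.where(ok, areas, np.inf)))
    return cand[idx]


def _greedy_kgon(points: np.ndarray, k: int) -> np.ndarray:
    """Enclosing k-gon by repeatedly flattening the cheapest hull edge.

    Removing an edge extends its two neighbours to their intersection;
    the edge whose removal adds the least area goes first.  A documented
    heuristic: containment is exact, minimality approximate.
    """
    poly = list(_hull_ccw(points))
    while len(poly) > k:
        n = len(poly)
        best_cost, best_i, best_p = math.inf, None, None
        for i in range(n):
            a, b = poly[i], poly[(i + 1) % n]
            pa, da = poly[i - 1], np.asarray(a) - np.asarray(poly[i - 1])
            pb, db = poly[(i + 1) % n], np.asarray(poly[(i + 2) % n]) - np.asarray(b)
            p = _line_intersection(np.asarray(pa), da, np.asarray(pb), db)
            if p is None:
                continue
            # intersection must lie outward of the removed edge
            tri = np.array([a, p, b])
            cross = (p[0] - a[0]) * (b[1] - a[1]) - (p[1] - a[1]) * (b[0] - a[0])
            if cross < 0:
                continue
            cost = _poly_area(tri)
            if cost < best_cost:
                best_cost, best_i, best_p = cost, i, p
        if best_i is None:
            raise ValueError(f"cannot reduce enclosing polygon to {k} vertices")
        n = len(poly)
        keep = [poly[j] for j in range(n) if j not in (best_i, (best_i + 1) % n)]
        insert_at = best_i if best_i < (best_i + 1) % n else 0
        keep.insert(insert_at, best_p)
        poly = keep
    return _orient_ccw(np.array(poly))


def min_enclosing_polygon(points, k: int = 3) -> np.ndarray:
    """Minimal-area convex k-gon containing all points.

    k = 3 uses the exact flush-side search; k > 3 a greedy edge-
    flattening heuristic.  If the convex hull already has <= k vertices
    it is returned unchanged.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    hull = _hull_ccw(pts)
    if len(hull) <= k:
        return hull
    if k == 3:
        return _orient_ccw(_min_triangle(pts))
    return _greedy_kgon(pts, k)


def t_ratio(points, polygon) -> float:
    """Data-hull area over enclosing-polygon area; 1 means the data fill
    the polygon exactly (strong polytope/archetype structure)."""
    pts = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    p_area = _poly_area(poly)
    if p_area <= 0:
        raise ValueError("enclosing polygon has zero area")
    return _poly_area(_hull_ccw(pts)) / p_area


def archetype_analysis(Y_std, k: int = 3, n_rand: int = 10000,
                       seed: int = 0) -> ArchetypeResult:
    """Archetype identification with a column-permutation randomization test.

    Null datasets permute each trait column independently, preserving
    every marginal distribution but destroying between-trait
    correlation; each null set is re-ordinated and re-fitted, and
    p = (1 + #{t_rand >= t_obs}) / (1 + n_rand).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    Y = np.asarray(Y_std, dtype=float)
    scores = ordinate_2d(Y)
    polygon = min_enclosing_polygon(scores, k)
    t_obs = t_ratio(scores, polygon)

    rng = np.random.default_rng(seed)
    count = 0
    n, p = Y.shape
    for _ in range(n_rand):
        Yp = np.column_stack([Y[rng.permutation(n), j] for j in range(p)])
        try:
            s = ordinate_2d(Yp)
            t_r = t_ratio(s, min_enclosing_polygon(s, k))
        except ValueError:
            continue  # degenerate randomization; conservatively uncounted
        if t_r >= t_obs - 1e-12:
            count += 1
    p_random = (1 + count) / (1 + n_rand)

    nearest = []
    for v in polygon:
        d = np.hypot(scores[:, 0] - v[0], scores[:, 1] - v[1])
        i = int(np.argmin(d))
        nearest.append((i, float(d[i])))

    return ArchetypeResult(scores=scores, k=k, polygon=polygon, t_ratio=t_obs,
                           p_random=p_random, n_randomizations=n_rand,
                           nearest_samples=nearest, seed=seed)


def k_scan(Y_std, ks=(3, 4, 5), n_rand: int = 1000, seed: int = 0) -> list[ArchetypeResult]:
    """Archetype fits over a range of polygon orders."""
    return [archetype_analysis(Y_std, k=k, n_rand=n_rand, seed=seed + k) for k in ks]
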