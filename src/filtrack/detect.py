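"""Per-frame extraction of the curve network from intensity images.

Centerlines are obtained by a ridge tracer: the image is Gaussian-smoothed,
thresholded and skeletonized, and the skeleton is decomposed into
inter-junction branch polylines.  Points are then refined transverse to the
curve by an intensity-centroid correction, resampled at uniform arc-length
spacing, and short traces discarded.

Collisions between curves are clustered into junctions, curves are dissected
there, and near-closed traces are marked as rings.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .model import (
    Curve,
    DetectionParams,
    Junction,
    Tip,
    TipEnd,
    curve_length,
    make_tip,
    resample_curve,
)

__all__ = [
    "extract_centerlines",
    "detect_junctions",
    "dissect_at_junctions",
    "close_loops",
]

_MIN_SPUR = 4  # terminal skeleton branches shorter than this are pruned


def _neighbor_offsets(ndim: int) -> np.ndarray:
    grids = np.meshgrid(*([[-1, 0, 1]] * ndim), indexing="ij")
    offs = np.stack([g.ravel() for g in grids], axis=1)
    return offs[np.any(offs != 0, axis=1)]


def _trace_skeleton(skel: np.ndarray, intensity: np.ndarray) -> list[np.ndarray]:
    """Decompose the skeleton into inter-junction branch polylines.

    Skeleton voxels with three or more neighbors (8-/26-connectivity) are
    junction voxels; adjacent junction voxels are merged into junction
    nodes.  Every maximal chain of ordinary voxels between junction nodes
    or free ends becomes one polyline, extended to the junction-node
    centroid at ends that touch one so that incident branch tips meet.
    Short terminal branches (skeleton spurs) are pruned and pure cycles are
    traced as near-closed polylines.  Curves deliberately stop at
    junctions: re-linking them across junctions is the local-matching
    stage's task.
    """
    coords = [tuple(c) for c in np.argwhere(skel).tolist()]
    if not coords:
        return []
    skel_set = set(coords)
    offsets = [tuple(o) for o in _neighbor_offsets(skel.ndim).tolist()]
    nbrs = {
        v: sorted(n for n in (tuple(np.add(v, o)) for o in offsets) if n in skel_set)
        for v in coords
    }
    junction_voxels = {v for v in coords if len(nbrs[v]) >= 3}

    # merge adjacent junction voxels into junction nodes
    node_of: dict[tuple[int, ...], int] = {}
    node_members: list[list[tuple[int, ...]]] = []
    for v in sorted(junction_voxels):
        if v in node_of:
            continue
        stack, members = [v], []
        node_id = len(node_members)
        node_of[v] = node_id
        while stack:
            u = stack.pop()
            members.append(u)
            for w in nbrs[u]:
                if w in junction_voxels and w not in node_of:
                    node_of[w] = node_id
                    stack.append(w)
        node_members.append(sorted(members))
    centroids = [np.mean(m, axis=0) for m in node_members]

    visited: set[tuple[int, ...]] = set()  # ordinary voxels only
    raw: list[tuple[list, int | None, int | None]] = []  # chain, start node, end node

    def walk(entry, first, entry_node):
        """Follow ordinary voxels from ``first`` until a junction or dead end."""
        chain = ([entry] if entry is not None else []) + [first]
        visited.add(first)
        prev, cur = entry, first
        while True:
            end_node = None
            step = None
            for w in nbrs[cur]:
                if w == prev:
                    continue
                if w in junction_voxels:
                    # close onto a junction; avoid instantly re-entering the
                    # node we started from
                    if node_of[w] != entry_node or len(chain) > 2:
                        end_node = node_of[w]
                        chain.append(w)
                        return chain, end_node
                elif w not in visited:
                    step = w
            if step is None:
                return chain, None
            chain.append(step)
            visited.add(step)
            prev, cur = cur, step

    # branches emanating from junction nodes
    for node_id, members in enumerate(node_members):
        for v in members:
            for w in nbrs[v]:
                if w in junction_voxels or w in visited:
                    continue
                chain, end_node = walk(v, w, node_id)
                raw.append((chain, node_id, end_node))
    # isolated open chains (touching no junction)
    ordinary = sorted(skel_set - junction_voxels)
    for v in ordinary:
        if v in visited or len(nbrs[v]) > 1:
            continue
        if len(nbrs[v]) == 0:
            visited.add(v)
            continue
        chain, end_node = walk(None, v, None)
        raw.append((chain, None, end_node))
    # remaining untouched voxels form pure cycles
    for v in ordinary:
        if v in visited:
            continue
        chain = [v]
        visited.add(v)
        prev, cur = None, v
        while True:
            nxt = [w for w in nbrs[cur] if w != prev and w not in visited]
            if not nxt:
                break
            chain.append(nxt[0])
            visited.add(nxt[0])
            prev, cur = cur, nxt[0]
        if len(chain) >= 3:
            raw.append((chain, None, None))

    paths: list[np.ndarray] = []
    for chain, a, b in raw:
        pts = [np.asarray(p, dtype=float) for p in chain]
        n_ordinary = len(chain) - (a is not None) - (b is not None)
        terminal = (a is None) or (b is None)
        isolated = (a is None) and (b is None)
        if terminal and not isolated and n_ordinary < _MIN_SPUR:
            continue  # skeleton spur
        if a is not None:
            pts[0] = centroids[a]
        if b is not None:
            pts[-1] = centroids[b]
        if len(pts) >= 2:
            paths.append(np.asarray(pts))
    return paths


def _smooth_polyline(pts: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Endpoint-preserving 3-point box smoothing to relax voxel jaggedness."""
    out = pts.copy()
    for _ in range(iterations):
        if len(out) < 3:
            break
        inner = (out[:-2] + out[1:-1] + out[2:]) / 3.0
        out = np.vstack([out[:1], inner, out[-1:]])
    return out


def _refine_transverse(
    curve: Curve,
    smooth_img: np.ndarray,
    radius: float = 3.0,
    iterations: int = 3,
) -> Curve:
    """Pull each curve point onto the intensity ridge center.

    At every point the smoothed image is sampled on a grid spanning the
    plane (3D) or line (2D) perpendicular to the local tangent, and the
    point moves to the intensity-weighted centroid of that transverse
    profile (background level subtracted).  Corrections are purely
    transverse so points cannot slide along the curve, and are clipped to
    one pixel per iteration.
    """
    from .model import point_tangents

    img = smooth_img
    ndim = img.ndim
    offsets_1d = np.linspace(-radius, radius, int(2 * radius) + 1)
    pts = curve.points.copy()
    for _ in range(iterations):
        work = Curve(id=curve.id, frame=curve.frame, points=pts, closed=curve.closed)
        tangents = point_tangents(work)
        # orthonormal transverse basis per point
        ref = np.zeros_like(tangents)
        smallest = np.argmin(np.abs(tangents), axis=1)
        ref[np.arange(len(ref)), smallest] = 1.0
        e1 = np.cross(tangents, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        if ndim == 2:
            # in-plane normal only
            e1 = np.column_stack([-tangents[:, 1], tangents[:, 0], np.zeros(len(pts))])
            bases = [e1]
        else:
            e2 = np.cross(tangents, e1)
            bases = [e1, e2]
        if len(bases) == 1:
            grid = offsets_1d[:, None]  # (m, 1)
        else:
            a, b = np.meshgrid(offsets_1d, offsets_1d, indexing="ij")
            grid = np.column_stack([a.ravel(), b.ravel()])  # (m, 2)
        # sample positions: (n, m, 3)
        samples = pts[:, None, :] + sum(
            grid[None, :, k, None] * bases[k][:, None, :] for k in range(len(bases))
        )
        flat = samples.reshape(-1, 3)
        vals = ndimage.map_coordinates(
            img, _xyz_to_index(flat, ndim).T, order=3, mode="nearest"
        ).reshape(len(pts), -1)
        w = np.maximum(vals - vals.min(axis=1, keepdims=True), 0.0)
        total = w.sum(axis=1)
        total[total <= 0] = 1.0
        shift_coeff = (w @ grid) / total[:, None]  # (n, len(bases))
        corr = sum(shift_coeff[:, k, None] * bases[k] for k in range(len(bases)))
        norms = np.linalg.norm(corr, axis=1)
        over = norms > 1.0
        corr[over] /= norms[over, None]
        pts = pts + corr
    return Curve(id=curve.id, frame=curve.frame, points=pts, closed=curve.closed)


def _index_to_xyz(idx: np.ndarray, ndim: int) -> np.ndarray:
    """Array indices ((y,x) or (z,y,x)) -> (x, y, z) points."""
    idx = np.atleast_2d(idx)
    if ndim == 2:
        return np.column_stack([idx[:, 1], idx[:, 0], np.zeros(len(idx))])
    return np.column_stack([idx[:, 2], idx[:, 1], idx[:, 0]])


def _xyz_to_index(pts: np.ndarray, ndim: int) -> np.ndarray:
    if ndim == 2:
        return np.column_stack([pts[:, 1], pts[:, 0]])
    return np.column_stack([pts[:, 2], pts[:, 1], pts[:, 0]])


def extract_centerlines(
    image: np.ndarray, params: DetectionParams, frame: int = 0
) -> list[Curve]:
    """Extract filament centerlines from a 2D image or 3D stack.

    Returns curves in (x, y, z) pixel coordinates, resampled at
    ``params.point_spacing``; traces shorter than ``params.min_curve_length``
    are dropped.  A blank image yields an empty list.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim not in (2, 3):
        raise ValueError("image must be 2D or 3D")
    smooth = ndimage.gaussian_filter(img, params.smoothing_sigma)
    mask = smooth >= params.ridge_threshold
    if not mask.any():
        return []
    skel = skeletonize(mask)
    paths = _trace_skeleton(skel, smooth)
    curves: list[Curve] = []
    next_id = 0
    for path in paths:
        pts = _index_to_xyz(path, img.ndim)
        pts = _smooth_polyline(pts)
        curve = Curve(id=next_id, frame=frame, points=pts, closed=False)
        if curve_length(curve) < params.min_curve_length:
            continue
        curve = _refine_transverse(curve, smooth)
        curve = resample_curve(curve, params.point_spacing)
        if len(curve) < 2:
            continue
        curve.id = next_id
        next_id += 1
        curves.append(curve)
    return curves


def detect_junctions(curves: list[Curve], params: DetectionParams) -> list[Junction]:
    """Cluster collision points between curves into network junctions.

    Any point of one curve within ``junction_radius`` of a non-adjacent
    point of another curve (or of the same curve, at least 4 index positions
    away) produces a collision point at the pair midpoint; collision points
    within twice the radius are merged by single linkage and each cluster
    becomes one junction at the collision centroid.
    """
    if not curves:
        return []
    all_pts = []
    owner = []
    for ci, c in enumerate(curves):
        for pi in range(len(c)):
            all_pts.append(c.points[pi])
            owner.append((ci, pi))
    all_pts = np.asarray(all_pts)
    tree = cKDTree(all_pts)
    collisions = []
    for a, b in tree.query_pairs(params.junction_radius):
        ca, pa = owner[a]
        cb, pb = owner[b]
        if ca == cb and abs(pa - pb) <= 3:
            continue
        collisions.append(0.5 * (all_pts[a] + all_pts[b]))
    if not collisions:
        return []
    collisions = np.asarray(collisions)
    # single-linkage merge within 2 * junction_radius via union-find
    parent = list(range(len(collisions)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    ctree = cKDTree(collisions)
    for a, b in ctree.query_pairs(2 * params.junction_radius):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[int, list[int]] = {}
    for i in range(len(collisions)):
        clusters.setdefault(find(i), []).append(i)
    junctions = []
    for jid, (_, idxs) in enumerate(sorted(clusters.items())):
        pos = collisions[idxs].mean(axis=0)
        tips = []
        for c in curves:
            for end in (TipEnd.HEAD, TipEnd.TAIL):
                p = c.head if end == TipEnd.HEAD else c.tail
                if np.linalg.norm(p - pos) <= 2 * params.junction_radius:
                    tips.append(make_tip(c, end))
        junctions.append(
            Junction(id=jid, frame=curves[0].frame, position=pos, tips=tips)
        )
    return junctions


def dissect_at_junctions(
    curves: list[Curve],
    junctions: list[Junction],
    cut_radius: float = 4.0,
) -> tuple[list[Curve], list[Junction]]:
    """Split every curve passing through a junction at its closest point.

    Cut points are duplicated into both resulting segments (total point
    count grows by one per cut).  Closed curves are reopened at their first
    cut.  Returned junctions carry tips of all segment ends within
    ``cut_radius`` of the junction position.
    """
    if not junctions:
        return list(curves), []
    next_id = max((c.id for c in curves), default=-1) + 1
    out: list[Curve] = []
    for c in curves:
        cuts: list[int] = []
        for j in junctions:
            d = np.linalg.norm(c.points - j.position, axis=1)
            k = int(np.argmin(d))
            if d[k] > cut_radius:
                continue
            if c.closed:
                cuts.append(k)
            elif 1 <= k <= len(c) - 2:
                cuts.append(k)
        cuts = sorted(set(cuts))
        # merge cut indices closer than 2 points apart
        merged: list[int] = []
        for k in cuts:
            if merged and k - merged[-1] < 2:
                continue
            merged.append(k)
        if not merged:
            out.append(c)
            continue
        if c.closed:
            # reopen the ring at the first cut, duplicating that point
            pts = np.roll(c.points, -merged[0], axis=0)
            pts = np.vstack([pts, pts[:1]])
            rel = sorted({(k - merged[0]) % len(c.points) for k in merged[1:]})
            rel = [k for k in rel if 1 <= k <= len(pts) - 2]
            pieces = _split_open(pts, rel)
        else:
            pieces = _split_open(c.points, merged)
        for i, piece in enumerate(pieces):
            if len(piece) < 2:
                continue
            cid = c.id if i == 0 else next_id
            if i > 0:
                next_id += 1
            out.append(Curve(id=cid, frame=c.frame, points=piece, closed=False))
    # each tip belongs to its nearest junction only, so no tip can be
    # paired independently at two junctions
    assigned: dict[int, list[Tip]] = {j.id: [] for j in junctions}
    for c in out:
        for end in (TipEnd.HEAD, TipEnd.TAIL):
            p = c.head if end == TipEnd.HEAD else c.tail
            dists = [(np.linalg.norm(p - j.position), j.id) for j in junctions]
            d, jid = min(dists)
            if d <= cut_radius:
                assigned[jid].append(make_tip(c, end))
    new_junctions = [
        Junction(id=j.id, frame=j.frame, position=j.position, tips=assigned[j.id])
        for j in junctions
    ]
    return out, new_junctions


def _split_open(points: np.ndarray, cuts: list[int]) -> list[np.ndarray]:
    bounds = [0] + list(cuts) + [len(points) - 1]
    return [points[a : b + 1] for a, b in zip(bounds[:-1], bounds[1:])]


def close_loops(curves: list[Curve], params: DetectionParams) -> list[Curve]:
    """Mark near-closed open curves as rings.

    An open curve whose tips lie within ``loop_close_gap`` of each other and
    whose outward tip tangents are anti-aligned (angle > 2*pi/3, i.e. the
    tips face each other across the gap) is flagged closed; an exactly
    duplicated endpoint is dropped.
    """
    out = []
    for c in curves:
        if c.closed or len(c) < 4:
            out.append(c)
            continue
        gap = np.linalg.norm(c.head - c.tail)
        if gap > params.loop_close_gap:
            out.append(c)
            continue
        th = make_tip(c, TipEnd.HEAD).tangent
        tt = make_tip(c, TipEnd.TAIL).tangent
        cos = float(np.clip(np.dot(th, tt), -1.0, 1.0))
        if np.arccos(cos) > 2 * np.pi / 3:
            pts = c.points
            if np.linalg.norm(pts[0] - pts[-1]) < 1e-6:
                pts = pts[:-1]
            out.append(Curve(id=c.id, frame=c.frame, points=pts, closed=True))
        else:
            out.append(c)
    return out
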