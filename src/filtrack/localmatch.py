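"""Topology-consistent splicing of dissected curves at network junctions.

Curve segments arriving at a junction are re-linked in pairs so that the
resulting partition of the network is smooth (tip tangents anti-aligned) and
temporally consistent (segments that were close to the same curve in the
previous frame prefer each other).  The pairing is a minimum-cost assignment
on two copies of the junction's tips, with dissimilarity

    D = D_ori + D_tem  in [0, 2],

where D_ori is 1 minus the normalized tip-tangent angle and D_tem compares
the segments' one-way distances to their closest previously matched curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .errors import InconsistentPairingError, InvalidCurveError, InvalidTipError
from .model import (
    Curve,
    Junction,
    NetworkFrame,
    Tip,
    TipEnd,
    point_tangents,
)

__all__ = [
    "TipPairing",
    "d_ori",
    "one_way_distance",
    "closest_prev_curve",
    "build_prev_assignment",
    "d_tem",
    "match_tips_at_junction",
    "splice",
]

# Cost placed on forbidden assignments (self-pairs); far above any D in [0, 2].
_FORBIDDEN = 1e6


@dataclass
class TipPairing:
    """Pairing decision at one junction: matched tip pairs plus leftovers."""

    junction_id: int
    pairs: list[tuple[Tip, Tip]] = field(default_factory=list)
    unpaired: list[Tip] = field(default_factory=list)


def d_ori(tip_i: Tip, tip_j: Tip) -> float:
    """Orientation dissimilarity in [0, 1].

    Tips of the same curve score 1 (a curve must not be spliced to itself
    through a junction); otherwise 1 - theta/pi where theta is the angle
    between the outward tip tangents.  Anti-parallel tangents (curves facing
    each other) score 0.
    """
    ti = np.asarray(tip_i.tangent, dtype=float)
    tj = np.asarray(tip_j.tangent, dtype=float)
    ni, nj = np.linalg.norm(ti), np.linalg.norm(tj)
    if ni == 0 or nj == 0:
        raise InvalidTipError("tip tangent has zero length")
    if tip_i.curve_id == tip_j.curve_id:
        return 1.0
    cos = float(np.clip(np.dot(ti / ni, tj / nj), -1.0, 1.0))
    theta = math.acos(cos)
    return 1.0 - theta / math.pi


def one_way_distance(
    u: Curve,
    r: Curve,
    u_tangents: np.ndarray | None = None,
    r_tangents: np.ndarray | None = None,
) -> float:
    """Asymmetric curve-to-curve distance weighting proximity by alignment.

    For each point y of u, take the distance to the nearest point z* of r
    attenuated by exp(-|cos phi|) with phi the angle between the tangents at
    y and z*; average over u.  Aligned nearby curves thus score lower than
    equally near but perpendicular ones.  Tangents are central differences
    (one-sided at open ends) unless precomputed arrays are supplied.
    """
    if len(u) == 0 or len(r) == 0:
        raise InvalidCurveError("one_way_distance requires non-empty curves")
    tu = point_tangents(u) if u_tangents is None else u_tangents
    tr = point_tangents(r) if r_tangents is None else r_tangents
    dist, idx = cKDTree(r.points).query(u.points)
    cos = np.abs(np.einsum("ij,ij->i", tu, tr[idx]))
    return float(np.mean(dist * np.exp(-cos)))


def closest_prev_curve(u: Curve, prev_frame: NetworkFrame | None) -> Curve | None:
    """The previous-frame (already spliced) curve nearest to u under the
    one-way distance; ties broken by ascending curve id; None if no
    predecessor frame or it is empty."""
    if prev_frame is None or not prev_frame.curves:
        return None
    best: Curve | None = None
    best_f = math.inf
    for r in sorted(prev_frame.curves, key=lambda c: c.id):
        f = one_way_distance(u, r)
        if f < best_f:
            best, best_f = r, f
    return best


def build_prev_assignment(
    curves: list[Curve], prev_frame: NetworkFrame | None
) -> dict[int, tuple[int, float]]:
    """For each curve, its closest previous-frame curve id and the one-way
    distance f to it.  Empty when there is no previous frame."""
    assign: dict[int, tuple[int, float]] = {}
    if prev_frame is None or not prev_frame.curves:
        return assign
    prev_sorted = sorted(prev_frame.curves, key=lambda c: c.id)
    prev_tangents = {r.id: point_tangents(r) for r in prev_sorted}
    for u in curves:
        tu = point_tangents(u)
        best_id, best_f = -1, math.inf
        for r in prev_sorted:
            f = one_way_distance(u, r, tu, prev_tangents[r.id])
            if f < best_f:
                best_id, best_f = r.id, f
        assign[u.id] = (best_id, best_f)
    return assign


def d_tem(
    tip_i: Tip,
    tip_j: Tip,
    prev_assign: dict[int, tuple[int, float]],
) -> float:
    """Temporal dissimilarity in [0, 1].

    1 when the two curves' closest previous curves differ; otherwise the
    absolute difference of their one-way distances f to that common curve,
    clamped to [0, 1] so it never exceeds the different-predecessor penalty.
    Without a previous frame the term is 0 and orientation alone decides.
    """
    if not prev_assign:
        return 0.0
    pi = prev_assign.get(tip_i.curve_id)
    pj = prev_assign.get(tip_j.curve_id)
    if pi is None or pj is None or pi[0] != pj[0]:
        return 1.0
    return float(min(1.0, abs(pi[1] - pj[1])))


def match_tips_at_junction(
    junction: Junction,
    curves: list[Curve],
    prev_frame: NetworkFrame | None = None,
    pair_cost_max: float = 0.9,
    ori_cost_max: float = 1.0 / 3.0,
) -> TipPairing:
    """Pair the tips incident at a junction by minimum-cost assignment.

    A complete bipartite graph over two copies of the tips is solved with
    the Hungarian algorithm on D = D_ori + D_tem; a pair is accepted only
    when matched in both directions (symmetrization) and its cost is below
    pair_cost_max.  Pairs whose orientation term alone reaches
    ``ori_cost_max`` are excluded outright: a spliced curve must continue
    smoothly through the junction (tip tangents at least 120 degrees apart
    for the default 1/3), which keeps leftover tips from pairing
    promiscuously when the temporal term cannot arbitrate.  Self-pairs are
    always excluded.
    """
    tips = list(junction.tips)
    n = len(tips)
    pairing = TipPairing(junction_id=junction.id)
    if n < 2:
        pairing.unpaired = tips
        return pairing
    tip_curves = {c.id: c for c in curves}
    prev_assign = build_prev_assignment(
        [tip_curves[t.curve_id] for t in tips if t.curve_id in tip_curves],
        prev_frame,
    )
    cost = np.full((n, n), _FORBIDDEN)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ori = d_ori(tips[i], tips[j])
            if ori >= ori_cost_max:
                continue
            cost[i, j] = ori + d_tem(tips[i], tips[j], prev_assign)
    rows, cols = linear_sum_assignment(cost)
    match = dict(zip(rows.tolist(), cols.tolist()))
    taken: set[int] = set()
    for i in range(n):
        j = match[i]
        if j > i and match.get(j) == i and cost[i, j] < pair_cost_max:
            pairing.pairs.append((tips[i], tips[j]))
            taken.update((i, j))
    pairing.unpaired = [tips[i] for i in range(n) if i not in taken]
    return pairing


def _chain_points(
    ordered: list[tuple[Curve, bool]], closed: bool
) -> np.ndarray:
    """Concatenate member curves (reversed when flagged), deduplicating the
    coincident cut points at the joins."""
    pieces: list[np.ndarray] = []
    for curve, reverse in ordered:
        pts = curve.points[::-1] if reverse else curve.points
        if pieces and np.linalg.norm(pieces[-1][-1] - pts[0]) < 1e-6:
            pts = pts[1:]
        pieces.append(pts)
    out = np.vstack(pieces)
    if closed and len(out) > 1 and np.linalg.norm(out[0] - out[-1]) < 1e-6:
        out = out[:-1]
    return out


def splice(frame: NetworkFrame, pairings: list[TipPairing]) -> NetworkFrame:
    """Concatenate curves transitively through paired tips.

    Chains of pairings become single spliced curves; a chain that closes on
    itself becomes a ring.  The returned frame keeps the dissected segments
    in ``segments`` and records dissected-id -> spliced-id in ``splice_map``.
    """
    curves = {c.id: c for c in frame.curves}
    # node = (curve_id, end); pairing edges link nodes across curves.
    partner: dict[tuple[int, TipEnd], tuple[int, TipEnd]] = {}
    for pairing in pairings:
        for ta, tb in pairing.pairs:
            na, nb = (ta.curve_id, ta.end), (tb.curve_id, tb.end)
            if na in partner or nb in partner:
                raise InconsistentPairingError(f"tip {na} or {nb} paired twice")
            if na[0] not in curves or nb[0] not in curves:
                continue
            partner[na] = nb
            partner[nb] = na

    def other_end(node):
        cid, end = node
        return (cid, TipEnd.TAIL if end == TipEnd.HEAD else TipEnd.HEAD)

    visited: set[int] = set()
    spliced: list[Curve] = []
    splice_map: dict[int, int] = {}

    def walk(start_node):
        """Follow internal/pairing edges from an entry node; returns the
        ordered member list and whether the chain closed into a ring."""
        ordered = []
        node = start_node
        while True:
            cid, end = node
            visited.add(cid)
            ordered.append((curves[cid], end == TipEnd.TAIL))
            exit_node = other_end(node)
            nxt = partner.get(exit_node)
            if nxt is None:
                return ordered, False
            if nxt[0] == start_node[0]:
                return ordered, True
            node = nxt

    for cid in sorted(curves):
        if cid in visited:
            continue
        start = (cid, TipEnd.HEAD)
        # For open chains, rewind to a free end so the walk covers everything.
        seen = {cid}
        node = start
        while True:
            back = partner.get(node)
            if back is None or back[0] in seen:
                break
            node = other_end(back)
            seen.add(back[0])
        ordered, ring = walk(node)
        members = [c.id for c, _ in ordered]
        if len(ordered) == 1 and not ring:
            c = ordered[0][0]
            new = Curve(id=c.id, frame=frame.frame, points=c.points.copy(), closed=c.closed)
        else:
            new_id = min(members)
            pts = _chain_points(ordered, ring)
            new = Curve(id=new_id, frame=frame.frame, points=pts, closed=ring)
        spliced.append(new)
        for m in members:
            splice_map[m] = new.id

    spliced.sort(key=lambda c: c.id)
    return NetworkFrame(
        frame=frame.frame,
        curves=spliced,
        junctions=frame.junctions,
        splice_map=splice_map,
        segments=list(frame.curves),
    )
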