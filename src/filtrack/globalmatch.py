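"""Temporal correspondence of curves as a minimum path cover of a k-partite graph.

Every extracted curve of every frame is a vertex; directed edges point
forward in time and are weighted by a symmetric average nearest-point
distance, inflated exponentially with the frame gap and saturated at eta.
The minimum path cover of this DAG is found exactly by reduction to
minimum-cost bipartite matching on two copies of the vertex set (Hungarian
algorithm); each path is one track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .errors import InvalidCurveError, InvalidEdgeError
from .model import Curve, NetworkFrame, Track, TrackingParams

__all__ = [
    "CorrespondenceGraph",
    "curve_distance",
    "edge_weight",
    "build_graph",
    "solve_path_cover",
]


def curve_distance(a: Curve, b: Curve) -> float:
    """Symmetric average nearest-point distance between two curves (pixels).

    Mean over a's points of the distance to the nearest point of b, averaged
    with the same quantity in the other direction (each direction weighted
    one half).
    """
    if len(a) == 0 or len(b) == 0:
        raise InvalidCurveError("curve_distance requires non-empty curves")
    d_ab = cKDTree(b.points).query(a.points)[0].mean()
    d_ba = cKDTree(a.points).query(b.points)[0].mean()
    return float(0.5 * d_ab + 0.5 * d_ba)


def edge_weight(a: Curve, b: Curve, params: TrackingParams) -> float:
    """Correspondence weight between a curve and a later curve.

    exp(c * (gap - 1)) * curve_distance, saturated at eta; the gap factor is
    1 for consecutive frames.
    """
    gap = b.frame - a.frame
    if gap <= 0:
        raise InvalidEdgeError("edge_weight requires frame(a) < frame(b)")
    w = math.exp(params.c * (gap - 1)) * curve_distance(a, b)
    return min(w, params.eta)


@dataclass
class CorrespondenceGraph:
    """k-partite DAG over curves of all frames.

    vertices : list of (frame, curve) in deterministic order
    edges : dict mapping (vertex_index_a, vertex_index_b) -> weight, with
        frame(a) < frame(b) and weight in (0, eta].
    """

    vertices: list[tuple[int, Curve]] = field(default_factory=list)
    edges: dict[tuple[int, int], float] = field(default_factory=dict)


def build_graph(frames: list[NetworkFrame], params: TrackingParams) -> CorrespondenceGraph:
    """Build the correspondence graph over spliced curves (grouping on) or
    dissected segments (grouping off).

    Edges are created for frame gaps 1..max_frame_gap; longer gaps would
    saturate at eta and carry no information.
    """
    graph = CorrespondenceGraph()
    for nf in frames:
        pool = nf.curves if params.grouping or not nf.segments else nf.segments
        for curve in sorted(pool, key=lambda c: c.id):
            graph.vertices.append((nf.frame, curve))
    n = len(graph.vertices)
    for i in range(n):
        fi, ci = graph.vertices[i]
        for j in range(n):
            fj, cj = graph.vertices[j]
            if 1 <= fj - fi <= params.max_frame_gap:
                graph.edges[(i, j)] = edge_weight(ci, cj, params)
    return graph


def solve_path_cover(graph: CorrespondenceGraph, params: TrackingParams) -> list[Track]:
    """Exact minimum path cover via bipartite reduction.

    A square cost matrix holds one row per vertex (as predecessor) and one
    column per vertex (as successor); absent, backward and intra-frame pairs
    cost eta.  The Hungarian algorithm yields a perfect matching; matched
    pairs cheaper than eta become successor links, pairs at eta are track
    breaks, and tracks are the maximal chains of links.  A matched weight of
    exactly eta means the pair is indistinguishable from "unrelated", which
    is the only reading under which isolated curves form zero-length tracks.
    """
    n = len(graph.vertices)
    if n == 0:
        return []
    cost = np.full((n, n), params.eta)
    for (i, j), w in graph.edges.items():
        cost[i, j] = w
    rows, cols = linear_sum_assignment(cost)
    successor: dict[int, int] = {}
    has_pred: set[int] = set()
    for i, j in zip(rows, cols):
        if cost[i, j] < params.eta:
            successor[i] = j
            has_pred.add(j)
    tracks: list[Track] = []
    for start in range(n):
        if start in has_pred:
            continue
        members = []
        v: int | None = start
        while v is not None:
            frame, curve = graph.vertices[v]
            members.append((frame, curve.id))
            v = successor.get(v)
        tracks.append(Track(id=len(tracks), members=members))
    return tracks
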