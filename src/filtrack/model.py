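"""Core domain types shared by all stages.

Coordinates are 0-based pixel centers in ``(x, y, z)`` order (column, row,
slice); 2D data carries ``z = 0``.  Anisotropic voxels are handled by scaling
coordinates with a voxel-size triple *before* any distance computation, so
every downstream metric operates in physical pixels of the xy plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import InvalidCurveError

__all__ = [
    "Curve",
    "Tip",
    "TipEnd",
    "Junction",
    "NetworkFrame",
    "Track",
    "TrackingParams",
    "DetectionParams",
    "curve_length",
    "resample_curve",
    "as_points",
    "point_tangents",
    "tip_tangent",
]


def as_points(points) -> np.ndarray:
    """Coerce input to an (n, 3) float array, padding 2D input with z = 0."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    if pts.shape[1] != 3:
        raise InvalidCurveError(f"points must be (n, 2) or (n, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise InvalidCurveError("points contain non-finite coordinates")
    return pts


@dataclass
class Curve:
    """An open or closed snake: an ordered point sequence on a filament.

    Parameters
    ----------
    id : int
        Identifier, unique within a frame.
    frame : int
        Temporal index (non-negative).
    points : (n, 3) ndarray
        Ordered points in pixel coordinates; n >= 2 for detected curves.
    closed : bool
        Whether the curve is a ring; the segment last -> first is implied
        and the first point is not repeated at the end.
    """

    id: int
    frame: int
    points: np.ndarray
    closed: bool = False

    def __post_init__(self):
        self.points = as_points(self.points)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def head(self) -> np.ndarray:
        return self.points[0]

    @property
    def tail(self) -> np.ndarray:
        return self.points[-1]


class TipEnd(str, Enum):
    HEAD = "head"
    TAIL = "tail"


@dataclass(frozen=True)
class Tip:
    """One end of an open curve, with its outward-pointing unit tangent."""

    curve_id: int
    end: TipEnd
    position: tuple[float, float, float]
    tangent: tuple[float, float, float]


@dataclass
class Junction:
    """A clustered collision point with references to incident curve tips."""

    id: int
    frame: int
    position: np.ndarray
    tips: list[Tip] = field(default_factory=list)


@dataclass
class NetworkFrame:
    """All curves and junctions of one timepoint.

    ``curves`` holds the current working set (dissected segments before
    splicing, spliced curves after).  ``segments`` preserves the dissected
    segments so that tracking can operate on them when grouping is disabled.
    ``splice_map`` maps each dissected-curve id to the spliced curve that
    absorbed it.
    """

    frame: int
    curves: list[Curve] = field(default_factory=list)
    junctions: list[Junction] = field(default_factory=list)
    splice_map: dict[int, int] = field(default_factory=dict)
    segments: list[Curve] = field(default_factory=list)

    def curve_by_id(self, cid: int) -> Curve:
        for c in self.curves:
            if c.id == cid:
                return c
        raise KeyError(cid)


@dataclass
class Track:
    """Temporal correspondence: an ordered list of (frame, curve_id) pairs.

    Frames are strictly increasing but need not be consecutive; a track of a
    single member (zero-length path) is valid.
    """

    id: int
    members: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        frames = [f for f, _ in self.members]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")


@dataclass
class TrackingParams:
    """Parameters of the correspondence stage.

    eta : float
        Saturation weight (pixels) beyond which curves are considered
        unrelated; default 20.
    c : float
        Frame-gap penalty rate (per frame); an edge across g frames is
        weighted by exp(c * (g - 1)).
    grouping : bool
        Track spliced (grouped) curves when True, inter-junction segments
        when False.  Local matching runs either way, to keep the detected
        topology temporally consistent.
    max_frame_gap : int
        Edges are only built for frame gaps up to this value; longer gaps
        saturate to eta by construction.
    pair_cost_max : float
        Local-matching pairs costing at least this much are rejected.
    """

    eta: float = 20.0
    c: float = 1.0
    grouping: bool = True
    max_frame_gap: int = 3
    pair_cost_max: float = 0.9

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if self.max_frame_gap < 1:
            raise ValueError("max_frame_gap must be a positive integer")


@dataclass
class DetectionParams:
    """Parameters of the per-frame centerline extraction.

    ridge_threshold : float
        Minimum smoothed intensity for a point to count as filament (the
        ridge threshold tau of the underlying contour method).
    smoothing_sigma : float
        Gaussian pre-smoothing scale in pixels.
    point_spacing : float
        Arc-length spacing of resampled curve points (pixels).
    junction_radius : float
        Collision radius for junction detection (pixels).
    min_curve_length : float
        Curves shorter than this are discarded (pixels).
    loop_close_gap : float
        Maximum tip-to-tip gap for closing a near-loop into a ring (pixels).
    """

    ridge_threshold: float = 10.0
    smoothing_sigma: float = 1.0
    point_spacing: float = 1.0
    junction_radius: float = 2.0
    min_curve_length: float = 5.0
    loop_close_gap: float = 3.0

    def __post_init__(self):
        for name in (
            "ridge_threshold",
            "smoothing_sigma",
            "point_spacing",
            "junction_radius",
            "min_curve_length",
            "loop_close_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _segment_lengths(points: np.ndarray, closed: bool) -> np.ndarray:
    diffs = np.diff(points, axis=0)
    seg = np.linalg.norm(diffs, axis=1)
    if closed:
        seg = np.append(seg, np.linalg.norm(points[0] - points[-1]))
    return seg


def curve_length(curve: Curve) -> float:
    """Total arc length of a curve in pixels (closing segment included for rings)."""
    if len(curve) < 2:
        raise InvalidCurveError("curve_length requires at least 2 points")
    return float(_segment_lengths(curve.points, curve.closed).sum())


def resample_curve(curve: Curve, spacing: float) -> Curve:
    """Resample a curve to arc-length-uniform spacing, preserving endpoints.

    The number of intervals is round(L / spacing) (at least 1), so the
    realized spacing differs from the request by less than 50% and the total
    length changes by less than ``spacing``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = curve.points
    if curve.closed:
        pts = np.vstack([pts, pts[:1]])
    seg = _segment_lengths(pts, closed=False)
    total = float(seg.sum())
    if total <= 0:
        raise InvalidCurveError("cannot resample a zero-length curve")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_int = max(1, round(total / spacing))
    s_new = np.linspace(0.0, total, n_int + 1)
    new = np.column_stack([np.interp(s_new, s, pts[:, k]) for k in range(3)])
    if curve.closed:
        new = new[:-1]
    return Curve(id=curve.id, frame=curve.frame, points=new, closed=curve.closed)


def point_tangents(curve: Curve) -> np.ndarray:
    """Unit tangent at every point: central differences, one-sided at open ends."""
    pts = curve.points
    n = len(pts)
    if n < 2:
        raise InvalidCurveError("tangents require at least 2 points")
    if curve.closed:
        t = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    else:
        t = np.empty_like(pts)
        t[1:-1] = pts[2:] - pts[:-2]
        t[0] = pts[1] - pts[0]
        t[-1] = pts[-1] - pts[-2]
    norms = np.linalg.norm(t, axis=1)
    norms[norms == 0] = 1.0
    return t / norms[:, None]


def tip_tangent(curve: Curve, end: TipEnd) -> np.ndarray:
    """Outward unit tangent at a curve end.

    Fit a least-squares line through the outermost min(5, ceil(n/2)) points;
    a single-segment difference would be dominated by point noise.
    """
    pts = curve.points
    n = len(pts)
    if n < 2:
        raise InvalidCurveError("tip tangent requires at least 2 points")
    k = min(5, -(-n // 2))
    k = max(k, 2)
    window = pts[:k] if end == TipEnd.HEAD else pts[-k:]
    centered = window - window.mean(axis=0)
    # First right-singular vector = direction of the fitted line.
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    # Orient outward: from the inner end of the window toward the tip.
    outward = window[0] - window[-1] if end == TipEnd.HEAD else window[-1] - window[0]
    if np.dot(direction, outward) < 0:
        direction = -direction
    return direction / np.linalg.norm(direction)


def make_tip(curve: Curve, end: TipEnd) -> Tip:
    pos = curve.head if end == TipEnd.HEAD else curve.tail
    tan = tip_tangent(curve, end)
    return Tip(
        curve_id=curve.id,
        end=end,
        position=tuple(float(v) for v in pos),
        tangent=tuple(float(v) for v in tan),
    )
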