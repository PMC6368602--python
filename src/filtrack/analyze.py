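"""Quantitative readouts of tracks: growth, constriction, alignment,
deformation recovery, and tracking accuracy."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    InsufficientDataError,
    IntegrityError,
    InvalidCurveError,
    InvalidParameterError,
)
from .groundtruth import GroundTruth
from .model import Curve, NetworkFrame, Track, curve_length, resample_curve

__all__ = [
    "LengthSeries",
    "RateFit",
    "EvaluationResult",
    "AngleDrift",
    "AxisPairOptions",
    "length_series",
    "fit_elongation_rate",
    "convert_elongation_rate",
    "constriction_rate",
    "nematic_order",
    "recover_affine",
    "angular_deviation_psi",
    "median_angular_deviation",
    "angle_drift",
    "map_curves_to_truth",
    "precision_recall",
    "evaluate_tracking",
]


@dataclass
class LengthSeries:
    """Per-track curve length by frame (frames strictly increasing)."""

    track_id: int
    samples: list[tuple[int, float]]


@dataclass
class RateFit:
    """Gaussian fit of per-frame length changes after zero-peak exclusion."""

    mean: float
    sigma: float
    n_used: int
    n_excluded: int


@dataclass
class EvaluationResult:
    """Link-level tracking accuracy against ground truth."""

    tp: int
    p: int
    fn: int

    @property
    def precision(self) -> float | None:
        return self.tp / self.p if self.p > 0 else None

    @property
    def recall(self) -> float:
        total = self.tp + self.fn
        return self.tp / total if total > 0 else 0.0


@dataclass
class AngleDrift:
    """Per-frame axis-angle changes, mean +/- std across track steps."""

    dazimuth_mean: float
    dazimuth_std: float
    dpolar_mean: float
    dpolar_std: float


def _find_curve(frames: list[NetworkFrame], frame: int, cid: int) -> Curve:
    for nf in frames:
        if nf.frame != frame:
            continue
        for c in nf.curves:
            if c.id == cid:
                return c
        for c in nf.segments:
            if c.id == cid:
                return c
    raise IntegrityError(f"no curve {cid} in frame {frame}")


def length_series(tracks: list[Track], frames: list[NetworkFrame]) -> list[LengthSeries]:
    """Curve length versus frame for every track."""
    out = []
    for t in tracks:
        samples = [
            (f, curve_length(_find_curve(frames, f, cid))) for f, cid in t.members
        ]
        out.append(LengthSeries(track_id=t.id, samples=samples))
    return out


def fit_elongation_rate(
    series: list[LengthSeries], exclusion_halfwidth: float = 3.0
) -> RateFit:
    """Gaussian fit of per-frame length changes, excluding the zero peak.

    Length changes are taken between consecutive track members (normalized
    by the frame gap); samples with |dL| below ``exclusion_halfwidth`` —
    the stall peak produced by curves that fail to advance past a junction —
    are dropped.  The Gaussian is then fitted by least squares to the
    histogram of the retained sample (1-px bins), which locates the main
    peak and is insensitive to the sparse far outliers that tracking errors
    produce; when too few bins are populated for a three-parameter fit the
    sample mean and standard deviation are reported directly.
    """
    dl = []
    for s in series:
        for (f0, l0), (f1, l1) in zip(s.samples, s.samples[1:]):
            dl.append((l1 - l0) / (f1 - f0))
    dl = np.asarray(dl)
    kept = dl[np.abs(dl) >= exclusion_halfwidth]
    if len(kept) == 0:
        raise InsufficientDataError("all length changes fall in the excluded zero peak")
    mean, sigma = _histogram_gaussian_fit(kept)
    return RateFit(
        mean=mean,
        sigma=sigma,
        n_used=len(kept),
        n_excluded=len(dl) - len(kept),
    )


def _histogram_gaussian_fit(sample: np.ndarray, bin_width: float = 1.0) -> tuple[float, float]:
    from scipy.optimize import curve_fit

    lo = math.floor(sample.min())
    hi = math.ceil(sample.max()) + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(sample, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    populated = np.count_nonzero(counts)
    if populated < 4:
        return float(sample.mean()), float(sample.std())

    def gauss(x, a, mu, s):
        return a * np.exp(-((x - mu) ** 2) / (2 * s**2))

    mode = centers[int(np.argmax(counts))]
    try:
        popt, _ = curve_fit(
            gauss, centers, counts,
            p0=(counts.max(), mode, 2.0), maxfev=10000,
        )
    except RuntimeError:
        return float(sample.mean()), float(sample.std())
    mu, sig = float(popt[1]), float(abs(popt[2]))
    # a near-flat histogram leaves the peak unconstrained; fall back
    if not (lo <= mu <= hi) or sig > (hi - lo):
        return float(sample.mean()), float(sample.std())
    return mu, sig


def convert_elongation_rate(
    px_per_frame: float,
    frame_interval_s: float,
    um_per_px: float,
    subunits_per_um: float,
) -> float:
    """Convert a pixel-per-frame elongation rate to subunits per second."""
    if frame_interval_s <= 0 or um_per_px <= 0 or subunits_per_um <= 0:
        raise InvalidParameterError("conversion factors must be positive")
    return px_per_frame / frame_interval_s * um_per_px * subunits_per_um


def constriction_rate(series: LengthSeries) -> float:
    """Slope of the ordinary least-squares line length(frame); negative for
    a constricting ring."""
    if len(series.samples) < 3:
        raise InsufficientDataError("constriction fit needs >= 3 points")
    f = np.array([s[0] for s in series.samples], dtype=float)
    l = np.array([s[1] for s in series.samples], dtype=float)
    return float(np.polyfit(f, l, 1)[0])


def nematic_order(data, segment_spacing: float = 2.0) -> float:
    """Nematic order parameter S of a set of axis directions.

    Accepts a list of curves (each contributes one unit direction per
    resampled segment) or an (n, 3) array of direction vectors.  S is the
    largest eigenvalue of Q = 3/2 <u u^T> - 1/2 I: 1 for perfect alignment,
    0 for an isotropic set, -1/2 for directions confined to the plane
    perpendicular to the eigenvector.  The eigenvalue construction makes S
    independent of the overall orientation of the sample.
    """
    if isinstance(data, np.ndarray) and data.ndim == 2:
        dirs = data.astype(float)
        if dirs.shape[1] == 2:
            dirs = np.column_stack([dirs, np.zeros(len(dirs))])
    else:
        pieces = []
        for c in data:
            rc = resample_curve(c, segment_spacing) if curve_length(c) > segment_spacing else c
            pieces.append(np.diff(rc.points, axis=0))
        if not pieces:
            raise InsufficientDataError("no direction vectors")
        dirs = np.vstack(pieces)
    norms = np.linalg.norm(dirs, axis=1)
    dirs = dirs[norms > 0] / norms[norms > 0, None]
    if len(dirs) < 2:
        raise InsufficientDataError("nematic order needs >= 2 directions")
    m = np.einsum("ni,nj->ij", dirs, dirs) / len(dirs)
    q = 1.5 * m - 0.5 * np.eye(3)
    return float(np.linalg.eigvalsh(q)[-1])


def _axis(curve: Curve) -> np.ndarray:
    e = curve.tail - curve.head
    n = np.linalg.norm(e)
    if n < 1e-12:
        raise InvalidCurveError("degenerate end-to-end axis")
    return e


def _track_axes(
    track: Track, frames: list[NetworkFrame]
) -> list[tuple[int, np.ndarray]]:
    out = []
    prev = None
    for f, cid in track.members:
        e = _axis(_find_curve(frames, f, cid))
        # keep orientation continuous along the track (detection may flip
        # the point order between frames)
        if prev is not None and np.dot(e, prev) < 0:
            e = -e
        out.append((f, e))
        prev = e
    return out


@dataclass
class AxisPairOptions:
    """Hygiene options for extracting comparable axis pairs from a track.

    trim_tolerance : when set, both curves of a pair are trimmed to their
        mutually overlapping extent (points within this distance of the
        other curve) before the axis is taken.  Detection does not always
        recover the same sub-extent of a filament in both frames; on a
        wiggly filament the axes of different sub-extents genuinely differ,
        so comparing untrimmed axes conflates detection extent with
        deformation.
    axis_method : "ends" (vector between the first and last point — exact
        under any affine map, for any curve shape) or "pca" (principal
        direction scaled by the projected extent — less sensitive to
        endpoint noise on quasi-straight snakes, but only exact for
        straight ones).
    max_link_distance : pairs whose curves are farther apart (symmetric
        mean nearest-point distance) are dropped as probable mislinks.
    min_axis_length : drop pairs with a shorter frame-k axis (pixels);
        short axes are orientation-noise dominated.
    max_extent_mismatch : drop pairs whose two axis lengths differ by more
        than this fraction (residual extent inconsistency).
    """

    trim_tolerance: float | None = None
    axis_method: str = "ends"
    max_link_distance: float | None = None
    min_axis_length: float = 0.0
    max_extent_mismatch: float = 1.0


def _extent_axis(points: np.ndarray, method: str) -> np.ndarray:
    if method == "ends":
        return points[-1] - points[0]
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if np.dot(d, points[-1] - points[0]) < 0:
        d = -d
    proj = centered @ d
    return d * (proj.max() - proj.min())


def _pair_axes(
    c0: Curve, c1: Curve, opts: AxisPairOptions
) -> tuple[np.ndarray, np.ndarray] | None:
    """Comparable (frame k, frame k+1) axes of one tracked pair, or None
    when the pair fails the hygiene gates."""
    from .globalmatch import curve_distance

    if opts.max_link_distance is not None:
        if curve_distance(c0, c1) > opts.max_link_distance:
            return None
    p0, p1 = c0.points, c1.points
    if opts.trim_tolerance is not None:
        d0 = cKDTree(p1).query(p0)[0]
        d1 = cKDTree(p0).query(p1)[0]
        in0 = np.where(d0 <= opts.trim_tolerance)[0]
        in1 = np.where(d1 <= opts.trim_tolerance)[0]
        if len(in0) < 3 or len(in1) < 3:
            return None
        p0 = p0[in0.min() : in0.max() + 1]
        p1 = p1[in1.min() : in1.max() + 1]
    e0 = _extent_axis(p0, opts.axis_method)
    e1 = _extent_axis(p1, opts.axis_method)
    if np.dot(e0, e1) < 0:
        e1 = -e1
    l0, l1 = np.linalg.norm(e0), np.linalg.norm(e1)
    if l0 < 1e-9 or l1 < 1e-9:
        return None
    if l0 < opts.min_axis_length:
        return None
    if abs(l1 - l0) / max(l0, l1) > opts.max_extent_mismatch:
        return None
    return e0, e1


def _consecutive_pairs(
    tracks: list[Track],
    frames: list[NetworkFrame],
    opts: AxisPairOptions,
    frame_k: int | None = None,
    gap: int = 1,
):
    """Yield (frame, e0, e1) axis pairs for consecutive track members."""
    for t in tracks:
        for (f0, c0id), (f1, c1id) in zip(t.members, t.members[1:]):
            if f1 - f0 != gap:
                continue
            if frame_k is not None and f0 != frame_k:
                continue
            c0 = _find_curve(frames, f0, c0id)
            c1 = _find_curve(frames, f1, c1id)
            pair = _pair_axes(c0, c1, opts)
            if pair is not None:
                yield f0, pair[0], pair[1]


def recover_affine(
    tracks: list[Track],
    frames: list[NetworkFrame],
    frame_k: int,
    n_triplets: int = 10,
    rng: np.random.Generator | None = None,
    max_condition: float = 100.0,
    options: AxisPairOptions | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Recover the affine matrix between frame_k and frame_k+1 from tracks.

    Each tracked snake is reduced to an axis (see AxisPairOptions).  For a
    triplet of tracks spanning both frames, the three frame-k axes
    (normalized to unit length, with the frame-k+1 axes scaled by the same
    factor so that an exact affine map is recovered exactly) form X and X',
    and the triplet's estimate is A = X' X^-1.  Ill-conditioned triplets
    (condition number above ``max_condition``, nearly coplanar directions)
    are rejected and redrawn.  Returns the element-wise mean and standard
    error over ``n_triplets`` triplets.
    """
    rng = rng or np.random.default_rng()
    opts = options or AxisPairOptions()
    usable = []
    for _, e0, e1 in _consecutive_pairs(tracks, frames, opts, frame_k=frame_k):
        scale = np.linalg.norm(e0)
        usable.append((e0 / scale, e1 / scale))
    if len(usable) < 3:
        raise InsufficientDataError("need >= 3 usable tracks spanning both frames")
    # Triplets are drawn without replacement while tracks last (each snake
    # contributes once, as in averaging disjoint triplets), refilling the
    # pool when exhausted; ill-conditioned draws are rejected and redrawn.
    estimates = []
    attempts = 0
    failures = 0
    available = list(range(len(usable)))
    while len(estimates) < n_triplets and attempts < 1000 * n_triplets:
        attempts += 1
        if len(available) < 3 or failures > 200:
            available = list(range(len(usable)))
            failures = 0
        idx = rng.choice(available, size=3, replace=False)
        x = np.column_stack([usable[i][0] for i in idx])
        xp = np.column_stack([usable[i][1] for i in idx])
        if np.linalg.cond(x) > max_condition:
            failures += 1
            continue
        failures = 0
        estimates.append(xp @ np.linalg.inv(x))
        available = [a for a in available if a not in set(idx.tolist())]
    if len(estimates) < n_triplets:
        raise InsufficientDataError("could not draw enough well-conditioned triplets")
    stack = np.stack(estimates)
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / math.sqrt(len(estimates))
    return mean, se


def angular_deviation_psi(
    track: Track,
    frames: list[NetworkFrame],
    imposed_matrix: np.ndarray,
    frame_k: int,
) -> float:
    """Angle (degrees, in [0, 90]) between a track's axis at frame_k+1 and
    the imposed-matrix image of its frame_k axis; axis sign is ignored."""
    axes = dict(_track_axes(track, frames))
    if frame_k not in axes or frame_k + 1 not in axes:
        raise InsufficientDataError("track does not span both frames")
    predicted = imposed_matrix @ axes[frame_k]
    observed = axes[frame_k + 1]
    cos = abs(np.dot(predicted, observed)) / (
        np.linalg.norm(predicted) * np.linalg.norm(observed)
    )
    return math.degrees(math.acos(min(1.0, cos)))


def median_angular_deviation(
    tracks: list[Track],
    frames: list[NetworkFrame],
    imposed_matrix: np.ndarray,
    options: AxisPairOptions | None = None,
) -> tuple[float, int]:
    """Median psi over all consecutive-frame pairs of all tracks; returns
    (median_degrees, n_pairs)."""
    opts = options or AxisPairOptions()
    psis = []
    for _, e0, e1 in _consecutive_pairs(tracks, frames, opts):
        predicted = imposed_matrix @ e0
        cos = abs(np.dot(predicted, e1)) / (
            np.linalg.norm(predicted) * np.linalg.norm(e1)
        )
        psis.append(math.degrees(math.acos(min(1.0, cos))))
    if not psis:
        raise InsufficientDataError("no tracked consecutive-frame pairs")
    return float(np.median(psis)), len(psis)


def angle_drift(
    tracks: list[Track],
    frames: list[NetworkFrame],
    options: AxisPairOptions | None = None,
) -> AngleDrift:
    """Per-frame change of the spherical angles of track axes.

    The azimuthal angle is taken modulo 180 degrees (an axis has no sign)
    and frame-to-frame differences are unwrapped into (-90, 90]; the polar
    angle is measured from the z axis folded into [0, 90].
    """
    opts = options or AxisPairOptions()
    dphis, dthetas = [], []
    for _, e0, e1 in _consecutive_pairs(tracks, frames, opts):
        phi0 = math.degrees(math.atan2(e0[1], e0[0])) % 180.0
        phi1 = math.degrees(math.atan2(e1[1], e1[0])) % 180.0
        dphi = ((phi1 - phi0 + 90.0) % 180.0) - 90.0
        th0 = math.degrees(math.acos(abs(e0[2]) / np.linalg.norm(e0)))
        th1 = math.degrees(math.acos(abs(e1[2]) / np.linalg.norm(e1)))
        dphis.append(dphi)
        dthetas.append(th1 - th0)
    if not dphis:
        return AngleDrift(0.0, 0.0, 0.0, 0.0)
    dphis = np.asarray(dphis)
    dthetas = np.asarray(dthetas)
    return AngleDrift(
        dazimuth_mean=float(dphis.mean()),
        dazimuth_std=float(dphis.std()),
        dpolar_mean=float(dthetas.mean()),
        dpolar_std=float(dthetas.std()),
    )


def map_curves_to_truth(
    frames: list[NetworkFrame],
    gt: GroundTruth,
    match_tolerance: float = 2.0,
    use_segments: bool = False,
) -> dict[tuple[int, int], int | None]:
    """Assign each detected curve to the ground-truth filament covering the
    majority of its points within ``match_tolerance`` pixels (None when no
    filament reaches a majority)."""
    mapping: dict[tuple[int, int], int | None] = {}
    for nf in frames:
        if nf.frame >= len(gt.frames):
            continue
        trees = {
            fid: cKDTree(pts) for fid, pts in gt.frames[nf.frame].items() if len(pts)
        }
        pool = nf.segments if use_segments and nf.segments else nf.curves
        for c in pool:
            best_fid, best_frac = None, 0.0
            for fid, tree in trees.items():
                d, _ = tree.query(c.points, distance_upper_bound=match_tolerance)
                frac = float(np.mean(np.isfinite(d)))
                if frac > best_frac:
                    best_fid, best_frac = fid, frac
            mapping[(nf.frame, c.id)] = best_fid if best_frac > 0.5 else None
    return mapping


def precision_recall(predicted_links, truth_links) -> EvaluationResult:
    """Link-level precision and recall.

    ``predicted_links`` are ((frame, fid), (frame', fid')) pairs already in
    ground-truth label space (fid may be None for unmatched curves); a link
    is a true positive when both endpoints map to the same filament.
    ``truth_links`` is the full set of true correspondences.
    """
    predicted = list(predicted_links)
    tp = sum(
        1 for (_, fa), (_, fb) in predicted if fa is not None and fa == fb
    )
    p = len(predicted)
    fn = max(0, len(list(truth_links)) - tp)
    return EvaluationResult(tp=tp, p=p, fn=fn)


def evaluate_tracking(
    tracks: list[Track],
    frames: list[NetworkFrame],
    gt: GroundTruth,
    match_tolerance: float = 2.0,
) -> EvaluationResult:
    """Map detected curves onto ground-truth filaments and score the
    tracks' consecutive-member links against the true correspondences."""
    mapping = map_curves_to_truth(frames, gt, match_tolerance)
    mapping_seg = map_curves_to_truth(frames, gt, match_tolerance, use_segments=True)
    mapping = {**mapping_seg, **mapping}
    predicted = []
    for t in tracks:
        for (f0, c0), (f1, c1) in zip(t.members, t.members[1:]):
            predicted.append(
                ((f0, mapping.get((f0, c0))), (f1, mapping.get((f1, c1))))
            )
    return precision_recall(predicted, gt.links)
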