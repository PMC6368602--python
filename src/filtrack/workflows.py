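"""End-to-end experiment drivers on synthetic data.

These functions tie the generators, the tracking pipeline and the analysis
readouts together at desk scale: a 256 x 256, 15-frame elongation movie and
100-voxel, ~30-fiber deformation stacks.  They are used both by the test
suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .analyze import (
    AxisPairOptions,
    fit_elongation_rate,
    angle_drift,
    length_series,
    median_angular_deviation,
    recover_affine,
)
from .model import DetectionParams, TrackingParams
from .pipeline import track_images
from .simulate2d import (
    FilamentState,
    GrowthParams,
    grow_filament_step,
    pooled_persistence_length,
    simulate_sequence,
)
from .simulate3d import DeformParams, NetworkGenParams, simulate_deformation_sequence

__all__ = [
    "persistence_experiment",
    "segment_acceptance_experiment",
    "elongation_experiment",
    "deformation_experiment",
]

# Detection settings for the 2D TIRFM-like renders: the blurred filament
# ridge peaks near 25 intensity units over a background of mean 5, so a
# threshold of 14 separates them cleanly.
DETECT_2D = dict(
    ridge_threshold=14.0,
    smoothing_sigma=1.0,
    point_spacing=1.0,
    junction_radius=2.0,
    min_curve_length=6.0,
    loop_close_gap=3.0,
)

# The 3D fiber renders have brighter ridges (peak ~ 25-30) and the same
# uniform background; the stronger smoothing stabilizes the skeleton of the
# thicker 3D tubes between frames.
DETECT_3D = dict(
    ridge_threshold=13.0,
    smoothing_sigma=1.5,
    point_spacing=1.0,
    junction_radius=2.0,
    min_curve_length=8.0,
    loop_close_gap=3.0,
)

# Axis-pair hygiene for deformation analyses: trim both snakes of a tracked
# pair to their overlapping extent, take the principal-axis extent vector,
# and drop probable mislinks (far pairs), short axes and extent mismatches.
# Triplets are drawn nearly orthogonal (condition <= 2.5) because the
# triplet solve amplifies axis noise by the condition number.
AXIS_HYGIENE = dict(
    trim_tolerance=4.0,
    axis_method="pca",
    max_link_distance=3.0,
    min_axis_length=8.0,
    max_extent_mismatch=0.15,
)
AFFINE_MAX_CONDITION = 2.5


def persistence_experiment(seed: int = 0, n_filaments: int = 500, n_segments: int = 2400):
    """Analytic and empirical persistence length of the 2D filament walk.

    Grows independent filaments (10 frames of growth each at the defaults)
    and fits the pooled tangent-correlation decay across all of them; a
    single walk carries only ~1 independent correlation sample at long
    separations, so the ensemble count controls the fit precision.
    Returns the formula value delta / sigma_theta^2 alongside the
    empirical fit.
    """
    params = GrowthParams(seed=seed)
    rng = np.random.default_rng(seed)
    walks = []
    for fid in range(n_filaments):
        f = FilamentState(fid=fid, points=np.zeros((1, 2)), direction=0.0)
        while f.n_segments < n_segments:
            grow_filament_step(f, params, rng)
        walks.append(f.points)
    return {
        "lp_formula": params.persistence_length,
        "lp_empirical": pooled_persistence_length(walks, delta=params.delta),
        "n_filaments": n_filaments,
    }


def segment_acceptance_experiment(seed: int = 0, n_frames: int = 1000):
    """Mean accepted segments per frame of the growth acceptance process."""
    params = GrowthParams(seed=seed)
    rng = np.random.default_rng(seed)
    f = FilamentState(fid=0, points=np.zeros((1, 2)), direction=0.0)
    counts = [grow_filament_step(f, params, rng) for _ in range(n_frames)]
    return {
        "mean_segments_per_frame": float(np.mean(counts)),
        "std_segments_per_frame": float(np.std(counts)),
        "n_frames": n_frames,
    }


def elongation_experiment(
    seed: int = 0,
    n_frames: int = 15,
    image_size: tuple[int, int] = (256, 256),
    exclusion_halfwidth: float = 3.0,
):
    """Full simulate -> detect -> track -> fit elongation pipeline.

    Returns the Gaussian fit of per-frame length changes (zero peak
    excluded) together with the generator's imposed rate.
    """
    growth = GrowthParams(seed=seed, n_frames=n_frames, image_size=image_size)
    images, gt = simulate_sequence(growth)
    det = DetectionParams(**DETECT_2D)
    trk = TrackingParams(grouping=True)
    frames, tracks = track_images(images, det, trk)
    series = length_series(tracks, frames)
    fit = fit_elongation_rate(series, exclusion_halfwidth)
    return {
        "rate_mean": fit.mean,
        "rate_sigma": fit.sigma,
        "n_used": fit.n_used,
        "n_excluded": fit.n_excluded,
        "imposed_rate": growth.elongation_rate,
        "n_tracks": len(tracks),
        "frames": frames,
        "tracks": tracks,
        "ground_truth": gt,
    }


def deformation_experiment(
    seed: int = 0,
    mode: str = "shear",
    n_steps: int = 4,
    box_size: float = 100.0,
    n_fibers: int = 30,
    grouping: bool = False,
    n_triplets: int = 10,
):
    """Simulate, track and analyze a deforming 3D fiber network.

    For shear, recovers the affine matrix between frames 0 and 1 from
    tracked snake triplets and the median angular deviation psi over all
    consecutive tracked pairs; for rotation, measures the per-frame drift
    of the azimuthal and polar axis angles.
    """
    net = NetworkGenParams(seed=seed, box_size=box_size, n_fibers=n_fibers)
    deform = DeformParams(mode=mode, n_steps=n_steps)
    stacks, gt, matrix = simulate_deformation_sequence(net, deform)
    det = DetectionParams(**DETECT_3D)
    trk = TrackingParams(grouping=grouping)
    frames, tracks = track_images(stacks, det, trk)
    opts = AxisPairOptions(**AXIS_HYGIENE)
    result = {
        "matrix": matrix,
        "frames": frames,
        "tracks": tracks,
        "ground_truth": gt,
        "n_tracks": len(tracks),
    }
    if mode == "shear":
        a_mean, a_se = recover_affine(
            tracks, frames, frame_k=0, n_triplets=n_triplets,
            rng=np.random.default_rng(seed + 17),
            max_condition=AFFINE_MAX_CONDITION,
            options=opts,
        )
        psi_median, n_pairs = median_angular_deviation(tracks, frames, matrix, opts)
        result.update(
            recovered_matrix=a_mean,
            recovered_se=a_se,
            psi_median=psi_median,
            n_pairs=n_pairs,
        )
    else:
        drift = angle_drift(tracks, frames, opts)
        result.update(drift=drift)
    return result
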