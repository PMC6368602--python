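"""Synthetic confocal stacks of a 3D fiber network under shear or rotation.

A geometric generator places quasi-straight fibers (unit-length segments
with a small Gaussian angular wiggle) at random positions and orientations
in a cubic box.  The network is then deformed frame by frame by a fixed
affine matrix — simple shear x' = x + lambda * z, or rotation about the z
axis — applied about the box center so the network stays in view; since all
analyses operate on end-to-end *vectors*, the centering offset is invisible
to them and the imposed matrix is recovered exactly in the noiseless limit.
Each frame is rendered by dense point deposition convolved with an
anisotropic Gaussian point spread function plus uniform voxel noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .groundtruth import GroundTruth

__all__ = [
    "NetworkGenParams",
    "DeformParams",
    "generate_network",
    "shear_step",
    "rotate_step",
    "deformation_matrix",
    "render_stack",
    "simulate_deformation_sequence",
]


@dataclass
class NetworkGenParams:
    """Conditions of the static fiber network and its rendering.

    box_size : cube side in pixels; voxel grid is box_size^3.
    n_fibers : number of fibers.
    fiber_length, fiber_length_spread : mean and uniform half-spread of
        fiber length (pixels).
    wiggle_sigma : per-segment angular wiggle (radians); 0 gives straight
        fibers.
    psf_sigma : (x, y, z) Gaussian PSF sigma in pixels.
    noise_max : per-voxel additive noise, Uniform(0, noise_max).
    brightness : intensity deposited per rendered point (spacing 0.3 px).
    """

    box_size: float = 100.0
    n_fibers: int = 30
    fiber_length: float = 40.0
    fiber_length_spread: float = 10.0
    wiggle_sigma: float = 0.02
    psf_sigma: tuple[float, float, float] = (1.5, 1.5, 1.5)
    noise_max: float = 10.0
    brightness: float = 130.0
    seed: int = 0


@dataclass
class DeformParams:
    """Per-frame affine deformation: shear of magnitude lam (x' = x +
    lam * z) or rotation by theta_deg about z, repeated n_steps times."""

    mode: str = "shear"  # "shear" | "rotation"
    lam: float = 0.05
    theta_deg: float = 3.5
    n_steps: int = 4

    def __post_init__(self):
        if self.mode not in ("shear", "rotation"):
            raise ValueError("mode must be 'shear' or 'rotation'")


def generate_network(params: NetworkGenParams) -> list[np.ndarray]:
    """Random fiber polylines, (n, 3) arrays in (x, y, z) pixels.

    Fiber centers are uniform over the whole box (small edge margin), as in
    a homogeneous network snapshot; fibers grow symmetrically from the
    center in unit steps with angular wiggle and stop growing at the box
    walls, so spatial density is uniform rather than concentrated in the
    middle.
    """
    rng = np.random.default_rng(params.seed)
    fibers = []
    box = params.box_size
    lo, hi = 2.0, box - 3.0
    for _ in range(params.n_fibers):
        length = params.fiber_length + rng.uniform(
            -params.fiber_length_spread, params.fiber_length_spread
        )
        center = rng.uniform(8.0, box - 8.0, size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        half = max(1, int(round(length / 2)))
        arms = []
        for sign in (1.0, -1.0):
            d = sign * direction
            p = center.copy()
            pts = []
            for _ in range(half):
                if params.wiggle_sigma > 0:
                    perturb = rng.normal(0.0, params.wiggle_sigma, size=3)
                    d = d + perturb
                    d = d / np.linalg.norm(d)
                step = p + d
                if np.any(step < lo) or np.any(step > hi):
                    break
                p = step
                pts.append(p.copy())
            arms.append(
                np.asarray(pts) if pts else np.empty((0, 3))
            )
        fiber = np.vstack([arms[1][::-1], center[None, :], arms[0]])
        if len(fiber) >= 2:
            fibers.append(fiber)
    return fibers


def shear_step(points: np.ndarray, lam: float) -> np.ndarray:
    """Simple shear (x, y, z) -> (x + lam * z, y, z)."""
    pts = np.asarray(points, dtype=float).copy()
    pts[:, 0] += lam * pts[:, 2]
    return pts


def rotate_step(points: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotation about the z axis by theta_deg degrees."""
    return np.asarray(points, dtype=float) @ deformation_matrix(
        DeformParams(mode="rotation", theta_deg=theta_deg)
    ).T


def deformation_matrix(params: DeformParams) -> np.ndarray:
    """The per-frame 3x3 matrix for the configured mode."""
    if params.mode == "shear":
        m = np.eye(3)
        m[0, 2] = params.lam
        return m
    th = math.radians(params.theta_deg)
    return np.array(
        [
            [math.cos(th), -math.sin(th), 0.0],
            [math.sin(th), math.cos(th), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )


def render_stack(
    fibers: list[np.ndarray],
    params: NetworkGenParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render fibers into a (z, y, x) intensity stack.

    Fibers are resampled at 0.3 px, deposited with trilinear weights,
    convolved with the anisotropic PSF, and uniform noise is added.  Points
    outside the box are clipped from the render only.
    """
    n = int(round(params.box_size))
    stack = np.zeros((n, n, n), dtype=float)
    for fiber in fibers:
        pts = _densify(fiber, 0.3)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        inside = (
            (x >= 0) & (x < n - 1) & (y >= 0) & (y < n - 1) & (z >= 0) & (z < n - 1)
        )
        pts = pts[inside]
        if len(pts) == 0:
            continue
        base = np.floor(pts).astype(int)
        frac = pts - base
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wgt = (
                        (frac[:, 0] if dx else 1 - frac[:, 0])
                        * (frac[:, 1] if dy else 1 - frac[:, 1])
                        * (frac[:, 2] if dz else 1 - frac[:, 2])
                    )
                    np.add.at(
                        stack,
                        (base[:, 2] + dz, base[:, 1] + dy, base[:, 0] + dx),
                        params.brightness * wgt,
                    )
    sx, sy, sz = params.psf_sigma
    stack = ndimage.gaussian_filter(stack, sigma=(sz, sy, sx))
    if params.noise_max > 0:
        stack += rng.uniform(0.0, params.noise_max, size=stack.shape)
    return stack


def _densify(polyline: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return polyline
    s_new = np.arange(0.0, total + spacing / 2, spacing)
    return np.column_stack(
        [np.interp(s_new, s, polyline[:, k]) for k in range(3)]
    )


def simulate_deformation_sequence(
    net: NetworkGenParams, deform: DeformParams
) -> tuple[list[np.ndarray], GroundTruth, np.ndarray]:
    """Render a network under successive affine steps.

    Returns n_steps + 1 stacks (frame 0 undeformed), ground truth with the
    exact fiber coordinates of every frame and identity correspondences,
    and the per-frame matrix.  The deformation is applied about the box
    center, so frame k equals the k-th matrix power acting on centered
    coordinates.
    """
    fibers = generate_network(net)
    matrix = deformation_matrix(deform)
    center = np.full(3, net.box_size / 2.0)
    rng = np.random.default_rng(net.seed + 1)
    stacks: list[np.ndarray] = []
    gt = GroundTruth()
    current = [f.copy() for f in fibers]
    for step in range(deform.n_steps + 1):
        if step > 0:
            current = [(f - center) @ matrix.T + center for f in current]
        stacks.append(render_stack(current, net, rng))
        gt.frames.append({i: f.copy() for i, f in enumerate(current)})
        gt.lengths.append(
            {
                i: float(np.linalg.norm(np.diff(f, axis=0), axis=1).sum())
                for i, f in enumerate(current)
            }
        )
    gt.build_links()
    return stacks, gt, matrix
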