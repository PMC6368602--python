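import numpy as np
import pytest

from filtrack.model import Curve, DetectionParams


def straight_curve(cid=0, frame=0, start=(0.0, 0.0), end=(10.0, 0.0), n=11, closed=False):
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = start + t * (end - start)
    return Curve(id=cid, frame=frame, points=pts, closed=closed)


def circle_curve(cid=0, frame=0, center=(0.0, 0.0), radius=10.0, n=36, closed=True,
                 theta0=0.0, theta1=2 * np.pi):
    th = np.linspace(theta0, theta1, n, endpoint=not closed)
    pts = np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )
    return Curve(id=cid, frame=frame, points=pts, closed=closed)


@pytest.fixture
def det_params():
    return DetectionParams(
        ridge_threshold=14.0,
        smoothing_sigma=1.0,
        point_spacing=1.0,
        junction_radius=2.0,
        min_curve_length=6.0,
        loop_close_gap=3.0,
    )


def render_filaments(point_sets, size=64, noise=0.0, brightness=100.0, seed=0):
    """Render polylines (densified) into a TIRFM-like test image."""
    from filtrack.simulate2d import FilamentState, GrowthParams, render_frame

    params = GrowthParams(
        image_size=(size, size), noise_max=noise, psf_sigma=1.5, brightness=1.0
    )
    rng = np.random.default_rng(seed)
    filaments = []
    for i, pts in enumerate(point_sets):
        pts = np.asarray(pts, dtype=float)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        s_new = np.arange(0.0, s[-1], 0.05)
        dense = np.column_stack([np.interp(s_new, s, pts[:, k]) for k in range(2)])
        f = FilamentState(fid=i, points=dense, direction=0.0)
        f.brightness = np.full(len(dense) - 1, brightness * 0.05)
        filaments.append(f)
    return render_frame(filaments, params, rng)
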