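import math

import numpy as np
import pytest

from filtrack.analyze import (
    AxisPairOptions,
    EvaluationResult,
    LengthSeries,
    angle_drift,
    angular_deviation_psi,
    constriction_rate,
    convert_elongation_rate,
    evaluate_tracking,
    fit_elongation_rate,
    length_series,
    nematic_order,
    precision_recall,
    recover_affine,
)
from filtrack.errors import (
    InsufficientDataError,
    IntegrityError,
    InvalidParameterError,
)
from filtrack.groundtruth import GroundTruth
from filtrack.model import Curve, NetworkFrame, Track

from conftest import straight_curve


def frames_with_tracked_curve(lengths):
    frames, members = [], []
    for f, l in enumerate(lengths):
        nf = NetworkFrame(frame=f)
        nf.curves.append(straight_curve(cid=0, frame=f, end=(l, 0), n=5))
        frames.append(nf)
        members.append((f, 0))
    return frames, [Track(id=0, members=members)]


class TestLengthSeries:
    def test_flat_series(self):
        frames, tracks = frames_with_tracked_curve([10, 10, 10])
        series = length_series(tracks, frames)
        assert [l for _, l in series[0].samples] == pytest.approx([10, 10, 10])

    def test_zero_length_track(self):
        frames, _ = frames_with_tracked_curve([10])
        series = length_series([Track(id=0, members=[(0, 0)])], frames)
        assert len(series[0].samples) == 1

    def test_dangling_reference(self):
        frames, _ = frames_with_tracked_curve([10])
        with pytest.raises(IntegrityError):
            length_series([Track(id=0, members=[(0, 99)])], frames)


class TestElongationFit:
    def test_recovers_contaminated_gaussian(self):
        rng = np.random.default_rng(0)
        dl = np.concatenate([rng.normal(12, 1.5, 1000), np.zeros(200)])
        series = [
            LengthSeries(track_id=i, samples=[(0, 0.0), (1, v)])
            for i, v in enumerate(dl)
        ]
        fit = fit_elongation_rate(series, exclusion_halfwidth=3.0)
        assert fit.mean == pytest.approx(12.0, abs=0.2)
        assert fit.sigma == pytest.approx(1.5, abs=0.3)
        assert fit.n_excluded >= 200

    def test_no_exclusion_plain_sample(self):
        series = [
            LengthSeries(track_id=i, samples=[(0, 0.0), (1, v)])
            for i, v in enumerate([10.0, 11.0, 12.0, 13.0, 14.0] * 4)
        ]
        fit = fit_elongation_rate(series, exclusion_halfwidth=1e-9)
        assert fit.mean == pytest.approx(12.0, abs=0.5)
        assert fit.n_excluded == 0

    def test_all_excluded_raises(self):
        series = [LengthSeries(track_id=0, samples=[(0, 5.0), (1, 5.0)])]
        with pytest.raises(InsufficientDataError):
            fit_elongation_rate(series, exclusion_halfwidth=3.0)


class TestRateConversion:
    def test_worked_example(self):
        rate = convert_elongation_rate(20.8, 120.0, 0.17, 370.0)
        assert round(rate, 1) == 10.9

    def test_zero_rate(self):
        assert convert_elongation_rate(0.0, 120.0, 0.17, 370.0) == 0.0

    def test_unit_factors(self):
        assert convert_elongation_rate(1.0, 1.0, 1.0, 370.0) == pytest.approx(370.0)

    def test_invalid_factor(self):
        with pytest.raises(InvalidParameterError):
            convert_elongation_rate(1.0, 0.0, 0.17, 370.0)


class TestConstriction:
    def test_exact_line(self):
        s = LengthSeries(track_id=0, samples=[(0, 30.0), (1, 28.0), (2, 26.0), (3, 24.0)])
        assert constriction_rate(s) == pytest.approx(-2.0)

    def test_flat(self):
        s = LengthSeries(track_id=0, samples=[(0, 5.0), (1, 5.0), (2, 5.0)])
        assert constriction_rate(s) == pytest.approx(0.0)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(1)
        samples = [(f, 40.0 - 0.8 * f + rng.normal(0, 0.1)) for f in range(30)]
        s = LengthSeries(track_id=0, samples=samples)
        assert constriction_rate(s) == pytest.approx(-0.8, rel=0.05)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            constriction_rate(LengthSeries(track_id=0, samples=[(0, 1.0), (1, 2.0)]))


class TestNematicOrder:
    def test_parallel_is_one(self):
        dirs = np.tile([1.0, 0.0, 0.0], (100, 1))
        assert nematic_order(dirs) == pytest.approx(1.0)

    def test_isotropic_near_zero(self):
        rng = np.random.default_rng(2)
        dirs = rng.normal(size=(100_000, 3))
        assert abs(nematic_order(dirs)) < 0.02

    def test_two_perpendicular_populations(self):
        dirs = np.vstack(
            [np.tile([1.0, 0, 0], (500, 1)), np.tile([0, 1.0, 0], (500, 1))]
        )
        assert nematic_order(dirs) == pytest.approx(0.25, abs=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        dirs = rng.normal(size=(500, 3))
        th = 0.7
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        assert nematic_order(dirs @ rot.T) == pytest.approx(nematic_order(dirs), abs=1e-9)

    def test_curves_input(self):
        curves = [straight_curve(cid=i, start=(0, i), end=(20, i)) for i in range(5)]
        assert nematic_order(curves) == pytest.approx(1.0, abs=1e-6)


def deformed_track_set(matrix, n=12, seed=0, center=None):
    """Noiseless tracks whose frame-1 curves are exact affine images."""
    rng = np.random.default_rng(seed)
    frames = [NetworkFrame(frame=0), NetworkFrame(frame=1)]
    tracks = []
    for i in range(n):
        start = rng.uniform(10, 90, size=3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts0 = start + np.outer(np.linspace(0, 20, 15), d)
        pts0 += rng.normal(0, 0.3, size=(15, 3)).cumsum(axis=0) * 0.05  # slight wiggle
        pts1 = pts0 @ matrix.T
        frames[0].curves.append(Curve(id=i, frame=0, points=pts0))
        frames[1].curves.append(Curve(id=i, frame=1, points=pts1))
        tracks.append(Track(id=i, members=[(0, i), (1, i)]))
    return frames, tracks


class TestRecoverAffine:
    @pytest.mark.parametrize(
        "matrix",
        [
            np.eye(3),
            np.array([[1, 0, 0.05], [0, 1, 0], [0, 0, 1.0]]),
            np.array(
                [
                    [math.cos(math.radians(3.5)), -math.sin(math.radians(3.5)), 0],
                    [math.sin(math.radians(3.5)), math.cos(math.radians(3.5)), 0],
                    [0, 0, 1.0],
                ]
            ),
            np.array([[1.1, 0.2, 0.0], [0.0, 0.9, -0.1], [0.05, 0.0, 1.05]]),
        ],
        ids=["identity", "shear", "rotation", "general"],
    )
    def test_exact_on_noiseless_tracks(self, matrix):
        frames, tracks = deformed_track_set(matrix)
        mean, se = recover_affine(
            tracks, frames, frame_k=0, rng=np.random.default_rng(5)
        )
        np.testing.assert_allclose(mean, matrix, atol=1e-6)

    def test_too_few_tracks(self):
        frames, tracks = deformed_track_set(np.eye(3), n=2)
        with pytest.raises(InsufficientDataError):
            recover_affine(tracks, frames, frame_k=0)


class TestAngularDeviation:
    def test_perfect_transform_zero(self):
        m = np.array([[1, 0, 0.05], [0, 1, 0], [0, 0, 1.0]])
        frames, tracks = deformed_track_set(m, n=3)
        psi = angular_deviation_psi(tracks[0], frames, m, frame_k=0)
        assert psi == pytest.approx(0.0, abs=1e-6)

    def test_known_rotation_against_identity(self):
        pts0 = np.outer(np.linspace(0, 20, 10), [1.0, 0, 0])
        th = math.radians(10)
        rot = np.array(
            [[math.cos(th), -math.sin(th), 0], [math.sin(th), math.cos(th), 0], [0, 0, 1.0]]
        )
        frames = [
            NetworkFrame(frame=0, curves=[Curve(id=0, frame=0, points=pts0)]),
            NetworkFrame(frame=1, curves=[Curve(id=0, frame=1, points=pts0 @ rot.T)]),
        ]
        track = Track(id=0, members=[(0, 0), (1, 0)])
        psi = angular_deviation_psi(track, frames, np.eye(3), frame_k=0)
        assert psi == pytest.approx(10.0, abs=1e-6)

    def test_axis_flip_ignored(self):
        pts0 = np.outer(np.linspace(0, 20, 10), [1.0, 0, 0])
        frames = [
            NetworkFrame(frame=0, curves=[Curve(id=0, frame=0, points=pts0)]),
            NetworkFrame(frame=1, curves=[Curve(id=0, frame=1, points=pts0[::-1])]),
        ]
        track = Track(id=0, members=[(0, 0), (1, 0)])
        psi = angular_deviation_psi(track, frames, np.eye(3), frame_k=0)
        assert psi == pytest.approx(0.0, abs=1e-9)


class TestAngleDrift:
    def test_exact_rotation_drift(self):
        th = math.radians(3.5)
        rot = np.array(
            [[math.cos(th), -math.sin(th), 0], [math.sin(th), math.cos(th), 0], [0, 0, 1.0]]
        )
        frames, tracks = deformed_track_set(rot, n=8, seed=3)
        drift = angle_drift(tracks, frames)
        assert drift.dazimuth_mean == pytest.approx(3.5, abs=1e-6)
        assert drift.dpolar_mean == pytest.approx(0.0, abs=1e-6)

    def test_static_network_no_drift(self):
        frames, tracks = deformed_track_set(np.eye(3), n=5, seed=4)
        drift = angle_drift(tracks, frames)
        assert drift.dazimuth_mean == pytest.approx(0.0, abs=1e-9)
        assert drift.dpolar_mean == pytest.approx(0.0, abs=1e-9)

    def test_azimuth_wrap_across_180(self):
        # axis at 178.8 degrees rotated by +3.5 crosses the 180 wrap
        phi0 = math.radians(178.8)
        d0 = np.array([math.cos(phi0), math.sin(phi0), 0.2])
        th = math.radians(3.5)
        rot = np.array(
            [[math.cos(th), -math.sin(th), 0], [math.sin(th), math.cos(th), 0], [0, 0, 1.0]]
        )
        pts0 = np.outer(np.linspace(0, 20, 10), d0)
        frames = [
            NetworkFrame(frame=0, curves=[Curve(id=0, frame=0, points=pts0)]),
            NetworkFrame(frame=1, curves=[Curve(id=0, frame=1, points=pts0 @ rot.T)]),
        ]
        drift = angle_drift([Track(id=0, members=[(0, 0), (1, 0)])], frames)
        assert drift.dazimuth_mean == pytest.approx(3.5, abs=1e-6)


class TestPrecisionRecall:
    def test_perfect_prediction(self):
        truth = [((0, 1), (1, 1)), ((0, 2), (1, 2))]
        res = precision_recall(truth, truth)
        assert res.precision == 1.0 and res.recall == 1.0

    def test_partial_counts(self):
        predicted = [((0, 1), (1, 1))] * 8 + [((0, 1), (1, 2))] * 2
        truth = [((0, k), (1, k)) for k in range(9)]
        res = precision_recall(predicted, truth)
        assert res.precision == pytest.approx(0.8)
        assert res.recall == pytest.approx(8 / 9)

    def test_empty_prediction(self):
        res = precision_recall([], [((0, 1), (1, 1))])
        assert res.precision is None
        assert res.recall == 0.0

    def test_evaluate_on_exact_detection(self):
        gt = GroundTruth()
        frames = []
        for f in range(3):
            pts = {i: np.column_stack([np.linspace(0, 20, 30), np.full(30, 10.0 * i), np.zeros(30)]) for i in range(2)}
            gt.frames.append(pts)
            gt.lengths.append({i: 20.0 for i in range(2)})
            nf = NetworkFrame(frame=f)
            for i in range(2):
                nf.curves.append(Curve(id=i, frame=f, points=pts[i]))
            frames.append(nf)
        gt.build_links()
        tracks = [Track(id=i, members=[(0, i), (1, i), (2, i)]) for i in range(2)]
        res = evaluate_tracking(tracks, frames, gt)
        assert res.precision == 1.0
        assert res.recall == 1.0
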