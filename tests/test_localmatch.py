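import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from filtrack.detect import detect_junctions, dissect_at_junctions
from filtrack.errors import InvalidTipError
from filtrack.localmatch import (
    build_prev_assignment,
    closest_prev_curve,
    d_ori,
    d_tem,
    match_tips_at_junction,
    one_way_distance,
    splice,
)
from filtrack.model import Curve, NetworkFrame, Tip, TipEnd, make_tip

from conftest import circle_curve, straight_curve


def tip(cid, tangent, pos=(0, 0, 0), end=TipEnd.HEAD):
    return Tip(curve_id=cid, end=end, position=tuple(pos), tangent=tuple(tangent))


class TestDOri:
    def test_same_curve_max_dissimilarity(self):
        assert d_ori(tip(1, (1, 0, 0)), tip(1, (-1, 0, 0), end=TipEnd.TAIL)) == 1.0

    def test_facing_tips_zero(self):
        assert d_ori(tip(1, (1, 0, 0)), tip(2, (-1, 0, 0))) == pytest.approx(0.0)

    def test_perpendicular_half(self):
        assert d_ori(tip(1, (1, 0, 0)), tip(2, (0, 1, 0))) == pytest.approx(0.5)

    def test_zero_tangent_rejected(self):
        with pytest.raises(InvalidTipError):
            d_ori(tip(1, (0, 0, 0)), tip(2, (1, 0, 0)))


class TestOneWayDistance:
    def test_identical_curve_zero(self):
        u = straight_curve()
        assert one_way_distance(u, u) == pytest.approx(0.0)

    def test_parallel_offset_attenuated(self):
        u = straight_curve(cid=0, start=(0, 0), end=(10, 0), n=11)
        r = straight_curve(cid=1, start=(0, 3), end=(10, 3), n=11)
        assert one_way_distance(u, r) == pytest.approx(3 * np.exp(-1), abs=1e-9)

    def test_perpendicular_tangents_unattenuated(self):
        u = straight_curve(cid=0, start=(0, 0), end=(10, 0), n=11)
        r = straight_curve(cid=1, start=(0, 3), end=(10, 3), n=11)
        perp = np.tile([0.0, 1.0, 0.0], (11, 1))
        assert one_way_distance(u, r, r_tangents=perp) == pytest.approx(3.0, abs=1e-9)


class TestClosestPrev:
    def test_single_candidate(self):
        u = straight_curve(cid=5)
        prev = NetworkFrame(frame=0, curves=[straight_curve(cid=1, start=(0, 2), end=(10, 2))])
        assert closest_prev_curve(u, prev).id == 1

    def test_prefers_coincident(self):
        u = straight_curve(cid=5)
        a = straight_curve(cid=1)
        b = straight_curve(cid=2, start=(0, 30), end=(10, 30))
        prev = NetworkFrame(frame=0, curves=[b, a])
        assert closest_prev_curve(u, prev).id == 1

    def test_tie_broken_by_smaller_id(self):
        u = straight_curve(cid=5)
        a = straight_curve(cid=2, start=(0, 4), end=(10, 4))
        b = straight_curve(cid=1, start=(0, -4), end=(10, -4))
        prev = NetworkFrame(frame=0, curves=[a, b])
        assert closest_prev_curve(u, prev).id == 1

    def test_empty_prev_frame(self):
        assert closest_prev_curve(straight_curve(), None) is None
        assert closest_prev_curve(straight_curve(), NetworkFrame(frame=0)) is None


class TestDTem:
    def test_different_previous_curves(self):
        assign = {1: (10, 0.3), 2: (11, 0.3)}
        assert d_tem(tip(1, (1, 0, 0)), tip(2, (-1, 0, 0)), assign) == 1.0

    def test_same_previous_equal_f(self):
        assign = {1: (10, 0.3), 2: (10, 0.3)}
        assert d_tem(tip(1, (1, 0, 0)), tip(2, (-1, 0, 0)), assign) == 0.0

    def test_same_previous_f_difference(self):
        assign = {1: (10, 0.3), 2: (10, 0.1)}
        assert d_tem(tip(1, (1, 0, 0)), tip(2, (-1, 0, 0)), assign) == pytest.approx(0.2)

    def test_no_previous_frame_neutral(self):
        assert d_tem(tip(1, (1, 0, 0)), tip(2, (-1, 0, 0)), {}) == 0.0


def _dissected_plus(det_params):
    a = straight_curve(cid=0, start=(-10, 0), end=(10, 0), n=21)
    b = straight_curve(cid=1, start=(0, -10), end=(0, 10), n=21)
    junctions = detect_junctions([a, b], det_params)
    segs, junctions = dissect_at_junctions([a, b], junctions)
    return segs, junctions


class TestMatchTips:
    def test_plus_junction_pairs_collinear(self, det_params):
        segs, junctions = _dissected_plus(det_params)
        pairing = match_tips_at_junction(junctions[0], segs)
        assert len(pairing.pairs) == 2
        assert not pairing.unpaired
        by_id = {c.id: c for c in segs}
        for ta, tb in pairing.pairs:
            ea = np.asarray(ta.tangent)
            eb = np.asarray(tb.tangent)
            # collinear continuation: outward tangents anti-aligned
            assert np.dot(ea, eb) < -0.9
            # and the two segments lie on the same original filament
            ca, cb = by_id[ta.curve_id], by_id[tb.curve_id]
            spread = np.vstack([ca.points, cb.points])
            assert min(np.ptp(spread[:, 0]), np.ptp(spread[:, 1])) < 1.0

    def test_t_junction_one_pair_one_leftover(self, det_params):
        bar = straight_curve(cid=0, start=(-10, 0), end=(10, 0), n=21)
        stem = straight_curve(cid=1, start=(0, 1), end=(0, 12), n=12)
        junctions = detect_junctions([bar, stem], det_params)
        segs, junctions = dissect_at_junctions([bar, stem], junctions)
        pairing = match_tips_at_junction(junctions[0], segs)
        assert len(pairing.pairs) == 1
        assert len(pairing.unpaired) == 1
        assert pairing.unpaired[0].curve_id == 1

    def test_temporal_cue_resolves_ambiguity(self, det_params):
        # an X crossing of two filaments at +-45 degrees: orientation alone
        # is symmetric, but proximity to the previous frame's curves decides
        a = Curve(id=0, frame=1, points=np.linspace((-10, -10, 0), (10, 10, 0), 21))
        b = Curve(id=1, frame=1, points=np.linspace((-10, 10, 0), (10, -10, 0), 21))
        junctions = detect_junctions([a, b], det_params)
        segs, junctions = dissect_at_junctions([a, b], junctions)
        prev = NetworkFrame(
            frame=0,
            curves=[
                Curve(id=0, frame=0, points=np.linspace((-10, -10, 0), (10, 10, 0), 21)),
                Curve(id=1, frame=0, points=np.linspace((-10, 10, 0), (10, -10, 0), 21)),
            ],
        )
        pairing = match_tips_at_junction(junctions[0], segs, prev_frame=prev)
        by_id = {c.id: c for c in segs}
        assign = build_prev_assignment(segs, prev)
        for ta, tb in pairing.pairs:
            assert assign[ta.curve_id][0] == assign[tb.curve_id][0]


class TestSplice:
    def test_plus_recovers_two_filaments(self, det_params):
        segs, junctions = _dissected_plus(det_params)
        frame = NetworkFrame(frame=0, curves=segs, junctions=junctions)
        pairing = match_tips_at_junction(junctions[0], segs)
        spliced = splice(frame, [pairing])
        assert len(spliced.curves) == 2
        lengths = sorted(
            np.linalg.norm(np.diff(c.points, axis=0), axis=1).sum()
            for c in spliced.curves
        )
        assert all(abs(l - 20.0) < 1.0 for l in lengths)
        assert set(spliced.splice_map) == {c.id for c in segs}

    def test_no_pairings_identity(self):
        curves = [straight_curve(cid=0), straight_curve(cid=1, start=(0, 5), end=(10, 5))]
        frame = NetworkFrame(frame=0, curves=curves)
        out = splice(frame, [])
        assert len(out.curves) == 2
        for a, b in zip(out.curves, curves):
            np.testing.assert_allclose(a.points, b.points)

    def test_ring_closure_from_three_arcs(self):
        arcs = []
        for i in range(3):
            arcs.append(
                circle_curve(
                    cid=i,
                    radius=10.0,
                    n=13,
                    closed=False,
                    theta0=i * 2 * np.pi / 3,
                    theta1=(i + 1) * 2 * np.pi / 3,
                )
            )
        frame = NetworkFrame(frame=0, curves=arcs)
        from filtrack.localmatch import TipPairing

        pairings = [
            TipPairing(
                junction_id=j,
                pairs=[(make_tip(arcs[j], TipEnd.TAIL), make_tip(arcs[(j + 1) % 3], TipEnd.HEAD))],
            )
            for j in range(3)
        ]
        out = splice(frame, pairings)
        assert len(out.curves) == 1
        assert out.curves[0].closed is True

    def test_point_count_conserved(self, det_params):
        segs, junctions = _dissected_plus(det_params)
        frame = NetworkFrame(frame=0, curves=segs, junctions=junctions)
        pairing = match_tips_at_junction(junctions[0], segs)
        spliced = splice(frame, [pairing])
        original = {tuple(p) for c in segs for p in c.points}
        after = {tuple(p) for c in spliced.curves for p in c.points}
        assert after == original


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_dissimilarity_symmetric_and_bounded(seed):
    rng = np.random.default_rng(seed)
    t1 = rng.normal(size=3)
    t2 = rng.normal(size=3)
    t1 /= np.linalg.norm(t1)
    t2 /= np.linalg.norm(t2)
    a, b = tip(1, t1), tip(2, t2)
    assign = {1: (9, rng.uniform(0, 2)), 2: (9, rng.uniform(0, 2))}
    dab = d_ori(a, b) + d_tem(a, b, assign)
    dba = d_ori(b, a) + d_tem(b, a, assign)
    assert dab == pytest.approx(dba, abs=1e-12)
    assert 0.0 <= dab <= 2.0


def test_repeated_frame_has_identical_topology(det_params):
    """Processing the same frame twice must splice it the same way."""
    from filtrack.model import TrackingParams
    from filtrack.pipeline import process_curves

    trk = TrackingParams()
    a = straight_curve(cid=0, start=(-10, 0), end=(10, 0), n=21)
    b = straight_curve(cid=1, start=(0, -10), end=(0, 10), n=21)
    f0 = process_curves([a, b], 0, det_params, trk, None)
    a2 = Curve(id=0, frame=1, points=a.points.copy())
    b2 = Curve(id=1, frame=1, points=b.points.copy())
    f1 = process_curves([a2, b2], 1, det_params, trk, f0)
    groups0 = sorted(
        sorted(d for d, s in f0.splice_map.items() if s == sid)
        for sid in set(f0.splice_map.values())
    )
    groups1 = sorted(
        sorted(d for d, s in f1.splice_map.items() if s == sid)
        for sid in set(f1.splice_map.values())
    )
    assert groups0 == groups1
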