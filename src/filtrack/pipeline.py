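"""End-to-end orchestration: detection -> local matching -> global tracking."""

from __future__ import annotations

import numpy as np

from .detect import close_loops, detect_junctions, dissect_at_junctions, extract_centerlines
from .globalmatch import build_graph, solve_path_cover
from .localmatch import match_tips_at_junction, splice
from .model import Curve, DetectionParams, NetworkFrame, Track, TrackingParams

__all__ = ["process_frame", "track_frames", "track_images"]


def process_frame(
    image: np.ndarray,
    frame_index: int,
    det: DetectionParams,
    trk: TrackingParams,
    prev_frame: NetworkFrame | None = None,
) -> NetworkFrame:
    """Detect and locally match one frame.

    Extracts centerlines, dissects them at detected junctions, pairs the
    incident tips (using the previously spliced frame as temporal context)
    and splices paired segments back into whole curves.  The returned frame
    holds the spliced curves, keeps the dissected segments for segment-level
    tracking, and records the splice map.
    """
    curves = extract_centerlines(image, det, frame=frame_index)
    return process_curves(curves, frame_index, det, trk, prev_frame)


def process_curves(
    curves: list[Curve],
    frame_index: int,
    det: DetectionParams,
    trk: TrackingParams,
    prev_frame: NetworkFrame | None = None,
) -> NetworkFrame:
    """Junction detection, dissection, local matching and splicing on
    pre-extracted curves of one frame."""
    junctions = detect_junctions(curves, det)
    segments, junctions = dissect_at_junctions(
        curves, junctions, cut_radius=2 * det.junction_radius
    )
    dissected = NetworkFrame(frame=frame_index, curves=segments, junctions=junctions)
    pairings = [
        match_tips_at_junction(j, segments, prev_frame, trk.pair_cost_max)
        for j in junctions
    ]
    spliced = splice(dissected, pairings)
    spliced.curves = close_loops(spliced.curves, det)
    return spliced


def track_frames(
    frames: list[NetworkFrame], trk: TrackingParams
) -> list[Track]:
    """Global k-partite correspondence over processed frames."""
    graph = build_graph(frames, trk)
    return solve_path_cover(graph, trk)


def track_images(
    images: list[np.ndarray],
    det: DetectionParams | None = None,
    trk: TrackingParams | None = None,
) -> tuple[list[NetworkFrame], list[Track]]:
    """Full pipeline over an image sequence."""
    det = det or DetectionParams()
    trk = trk or TrackingParams()
    frames: list[NetworkFrame] = []
    prev: NetworkFrame | None = None
    for i, img in enumerate(images):
        nf = process_frame(img, i, det, trk, prev)
        frames.append(nf)
        prev = nf
    tracks = track_frames(frames, trk)
    return frames, tracks
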