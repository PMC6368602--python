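"""Simulator-side ground truth: true centerlines and correspondences."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GroundTruth"]


@dataclass
class GroundTruth:
    """True filament trajectories and frame-to-frame correspondences.

    frames : one dict per frame mapping filament id -> (n, 3) centerline
        points in (x, y, z) pixel coordinates.
    lengths : one dict per frame mapping filament id -> true arc length
        (pixels), exact from the generator (not a polyline approximation).
    links : true correspondences ((frame, fid), (frame + 1, fid)) for every
        filament present in two consecutive frames.
    """

    frames: list[dict[int, np.ndarray]] = field(default_factory=list)
    lengths: list[dict[int, float]] = field(default_factory=list)
    links: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)

    def build_links(self) -> None:
        self.links = []
        for l in range(len(self.frames) - 1):
            for fid in self.frames[l]:
                if fid in self.frames[l + 1]:
                    self.links.append(((l, fid), (l + 1, fid)))
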