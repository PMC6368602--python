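"""File formats: TIFF image sequences in, plain-text curve/track files out.

The native result format is a line-oriented text file with ``#frame``,
``#curve``, ``#junctions`` and ``#tracks`` sections; coordinates are written
with six decimals and the reader inverts the writer exactly at that
precision.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, ParseError
from .model import Curve, Junction, NetworkFrame, TipEnd, Track, make_tip

__all__ = [
    "read_image_sequence",
    "write_image_sequence",
    "write_tracks",
    "read_tracks",
]


def read_image_sequence(path: str | os.PathLike) -> list[np.ndarray]:
    """Read a time series of images.

    A single multi-page TIFF is a 2D time series (one page per frame); a
    directory of per-timepoint TIFF stacks (sorted by name) is a 3D time
    series.  Mixed dimensionality raises FormatError.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FormatError(f"no TIFF files in directory {p}")
        frames = [np.asarray(tifffile.imread(f)) for f in files]
        dims = {f.ndim for f in frames}
        if len(dims) != 1:
            raise FormatError("mixed dimensionality across timepoint files")
        return frames
    if not p.exists():
        raise OSError(f"no such file: {p}")
    data = np.asarray(tifffile.imread(p))
    if data.ndim == 2:
        return [data]
    if data.ndim == 3:
        return [data[i] for i in range(data.shape[0])]
    raise FormatError(f"unsupported TIFF dimensionality {data.ndim}")


def write_image_sequence(path: str | os.PathLike, images: list[np.ndarray]) -> None:
    """Write a 2D series as one multi-page TIFF, or a 3D series as a
    directory of per-timepoint stacks named t000.tif, t001.tif, ..."""
    p = Path(path)
    ndim = images[0].ndim
    if ndim == 2:
        tifffile.imwrite(
            p,
            np.stack([i.astype(np.float32) for i in images]),
            photometric="minisblack",
        )
    elif ndim == 3:
        p.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(images):
            tifffile.imwrite(
                p / f"t{i:03d}.tif", img.astype(np.float32), photometric="minisblack"
            )
    else:
        raise FormatError("images must be 2D or 3D")


def write_tracks(
    path: str | os.PathLike,
    frames: list[NetworkFrame],
    tracks: list[Track] | None = None,
) -> None:
    """Write curves, junctions and tracks as the native text format."""
    with open(path, "w") as fh:
        fh.write("# filtrack result v1\n")
        for nf in frames:
            fh.write(f"#frame {nf.frame}\n")
            for c in nf.curves:
                fh.write(f"#curve {c.id} {int(c.closed)} {len(c)}\n")
                for p in c.points:
                    fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            fh.write(f"#junctions {len(nf.junctions)}\n")
            for j in nf.junctions:
                tips = " ".join(f"{t.curve_id}:{t.end.value}" for t in j.tips)
                fh.write(
                    f"{j.id} {j.position[0]:.6f} {j.position[1]:.6f} "
                    f"{j.position[2]:.6f} {tips}\n".rstrip() + "\n"
                )
        if tracks is not None:
            fh.write(f"#tracks {len(tracks)}\n")
            for t in tracks:
                row = " ".join(f"{f}:{cid}" for f, cid in t.members)
                fh.write(f"{t.id} {row}\n")


def read_tracks(path: str | os.PathLike) -> tuple[list[NetworkFrame], list[Track]]:
    """Read the native text format back; inverse of :func:`write_tracks`.

    A file without a ``#tracks`` section yields an empty track list.
    Junction tips are rebuilt from curve geometry where the referenced
    curve is present in the frame.
    """
    frames: list[NetworkFrame] = []
    tracks: list[Track] = []
    cur: NetworkFrame | None = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n = len(lines)

    def fail(msg, ln):
        raise ParseError(msg, line=ln + 1)

    while i < n:
        line = lines[i].strip()
        if not line or line.startswith("# "):
            i += 1
            continue
        if line.startswith("#frame"):
            parts = line.split()
            if len(parts) != 2:
                fail("malformed #frame header", i)
            cur = NetworkFrame(frame=int(parts[1]))
            frames.append(cur)
            i += 1
        elif line.startswith("#curve"):
            parts = line.split()
            if cur is None or len(parts) != 4:
                fail("malformed #curve header", i)
            cid, closed, npts = int(parts[1]), bool(int(parts[2])), int(parts[3])
            pts = []
            for k in range(npts):
                if i + 1 + k >= n:
                    fail("truncated curve block", i)
                vals = lines[i + 1 + k].split()
                if len(vals) != 3:
                    fail("truncated coordinate line", i + 1 + k)
                try:
                    pts.append([float(v) for v in vals])
                except ValueError:
                    fail("non-numeric coordinate", i + 1 + k)
            cur.curves.append(
                Curve(id=cid, frame=cur.frame, points=np.asarray(pts), closed=closed)
            )
            i += 1 + npts
        elif line.startswith("#junctions"):
            parts = line.split()
            if cur is None or len(parts) != 2:
                fail("malformed #junctions header", i)
            njunc = int(parts[1])
            by_id = {c.id: c for c in cur.curves}
            for k in range(njunc):
                if i + 1 + k >= n:
                    fail("truncated junction block", i)
                vals = lines[i + 1 + k].split()
                if len(vals) < 4:
                    fail("malformed junction line", i + 1 + k)
                jid = int(vals[0])
                pos = np.asarray([float(v) for v in vals[1:4]])
                tips = []
                for ref in vals[4:]:
                    cid_s, end_s = ref.split(":")
                    c = by_id.get(int(cid_s))
                    if c is not None and len(c) >= 2:
                        tips.append(make_tip(c, TipEnd(end_s)))
                cur.junctions.append(
                    Junction(id=jid, frame=cur.frame, position=pos, tips=tips)
                )
            i += 1 + njunc
        elif line.startswith("#tracks"):
            parts = line.split()
            if len(parts) != 2:
                fail("malformed #tracks header", i)
            ntr = int(parts[1])
            for k in range(ntr):
                if i + 1 + k >= n:
                    fail("truncated track block", i)
                vals = lines[i + 1 + k].split()
                members = []
                for ref in vals[1:]:
                    f_s, c_s = ref.split(":")
                    members.append((int(f_s), int(c_s)))
                tracks.append(Track(id=int(vals[0]), members=members))
            i += 1 + ntr
        else:
            fail(f"unrecognized line: {line[:40]!r}", i)
    return frames, tracks
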