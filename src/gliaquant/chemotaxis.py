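"""Directed process motility toward a point source (ATP / Aβ pipette).

Velocity semantics follow the manual-tracking convention: total path length
(sum of consecutive Euclidean step lengths, converted to µm) divided by the
elapsed time in minutes. A process that reaches the pipette is truncated at its
arrival point — post-arrival positions contribute neither distance nor time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .imaging import ImageStack, max_project_z
from .motility import binarize

__all__ = [
    "ProcessTrack",
    "VelocityResult",
    "track_velocity",
    "aggregate_cell",
    "auto_track_tips",
    "read_tracks_csv",
    "write_tracks_csv",
]

DEFAULT_CAPTURE_RADIUS_UM = 2.0


@dataclass(frozen=True)
class ProcessTrack:
    """Ordered (frame, x, y) tip positions for one tracked process, in pixels."""

    points: tuple[tuple[int, float, float], ...]
    cell_id: str = "cell0"
    track_id: str = "track0"
    pipette_xy: tuple[float, float] | None = None

    def __post_init__(self):
        pts = tuple((int(f), float(x), float(y)) for f, x, y in self.points)
        object.__setattr__(self, "points", pts)
        frames = [p[0] for p in pts]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class VelocityResult:
    per_process_velocity: tuple[float, ...]  # µm/min, NaN where undefined
    per_cell_velocity: float
    truncated_at_frame: tuple[int | None, ...] = ()
    n_defined: int = 0
    cell_id: str = ""


def track_velocity(
    track: ProcessTrack,
    pixel_size: float,
    frame_interval: float,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS_UM,
) -> tuple[float, int | None]:
    """Path-length velocity of one track in µm/min, with arrival truncation.

    If the track carries a pipette position, it is cut at the first point within
    ``capture_radius`` (µm) of the pipette; elapsed time ends there. Returns
    (velocity, truncation frame or None); velocity is NaN when fewer than two
    usable points remain.
    """
    if pixel_size <= 0 or frame_interval <= 0:
        raise ValueError("pixel_size and frame_interval must be positive")
    pts = list(track.points)
    trunc_frame: int | None = None
    if track.pipette_xy is not None:
        px, py = track.pipette_xy
        r_px = capture_radius / pixel_size
        for i, (f, x, y) in enumerate(pts):
            if math.hypot(x - px, y - py) <= r_px:
                pts = pts[: i + 1]
                trunc_frame = f
                break
    if len(pts) < 2:
        return math.nan, trunc_frame
    path_px = sum(
        math.hypot(x1 - x0, y1 - y0)
        for (_, x0, y0), (_, x1, y1) in zip(pts, pts[1:])
    )
    elapsed_min = (pts[-1][0] - pts[0][0]) * frame_interval / 60.0
    return path_px * pixel_size / elapsed_min, trunc_frame


def aggregate_cell(
    velocities: list[float],
    cell_id: str = "",
    truncations: list[int | None] | None = None,
) -> VelocityResult | None:
    """Per-cell velocity = arithmetic mean of its defined per-process velocities.

    Returns None when no process has a defined velocity (the cell is excluded).
    """
    defined = [v for v in velocities if not math.isnan(v)]
    if not defined:
        return None
    return VelocityResult(
        per_process_velocity=tuple(velocities),
        per_cell_velocity=float(np.mean(defined)),
        truncated_at_frame=tuple(truncations) if truncations else (None,) * len(velocities),
        n_defined=len(defined),
        cell_id=cell_id,
    )


def auto_track_tips(
    stack: ImageStack,
    pipette_xy: tuple[float, float],
    n_tips: int,
    search_radius_px: float = 6.0,
    threshold_method: str = "otsu_mean",
) -> list[ProcessTrack]:
    """Nearest-object tip tracker for synthetic chemotaxis stacks.

    At t0 the ``n_tips`` foreground objects nearest the pipette seed one track
    each (position = object centroid). Each subsequent frame, a tip is linked to
    the centroid of foreground pixels within ``search_radius_px`` of its previous
    position; a tip with no candidate in range terminates its track.
    """
    if n_tips < 1:
        raise ValueError("n_tips must be >= 1")
    work = max_project_z(stack) if "Z" in stack.axes else stack
    masks = binarize(work, method=threshold_method).masks
    px, py = pipette_xy
    lbl, n = ndi.label(masks[0])
    if n == 0:
        return []
    centroids = ndi.center_of_mass(masks[0], lbl, range(1, n + 1))  # (y, x)
    order = np.argsort([math.hypot(cx - px, cy - py) for cy, cx in centroids])
    seeds = [centroids[i] for i in order[: min(n_tips, n)]]
    tracks: list[ProcessTrack] = []
    ys, xs = np.mgrid[0 : masks.shape[1], 0 : masks.shape[2]]
    for k, (sy, sx) in enumerate(seeds):
        pts = [(0, float(sx), float(sy))]
        cy, cx = sy, sx
        for t in range(1, len(masks)):
            near = masks[t] & ((ys - cy) ** 2 + (xs - cx) ** 2 <= search_radius_px**2)
            if not near.any():
                break  # tip lost
            cy = float(ys[near].mean())
            cx = float(xs[near].mean())
            pts.append((t, cx, cy))
        tracks.append(ProcessTrack(points=tuple(pts), track_id=f"tip{k}", pipette_xy=(px, py)))
    return tracks


# ---------------------------------------------------------------------------
# CSV interchange (columns: track_id, cell_id, frame, x_px, y_px)
# ---------------------------------------------------------------------------

def write_tracks_csv(tracks: list[ProcessTrack], path: str | Path) -> None:
    rows = [
        {"track_id": tr.track_id, "cell_id": tr.cell_id, "frame": f, "x_px": x, "y_px": y}
        for tr in tracks
        for f, x, y in tr.points
    ]
    pd.DataFrame(rows, columns=["track_id", "cell_id", "frame", "x_px", "y_px"]).to_csv(path, index=False)


def read_tracks_csv(path: str | Path, pipette_xy: tuple[float, float] | None = None) -> list[ProcessTrack]:
    df = pd.read_csv(path)
    tracks = []
    for (tid, cid), grp in df.groupby(["track_id", "cell_id"], sort=False):
        grp = grp.sort_values("frame")
        pts = tuple(zip(grp["frame"].astype(int), grp["x_px"].astype(float), grp["y_px"].astype(float)))
        tracks.append(ProcessTrack(points=pts, cell_id=str(cid), track_id=str(tid), pipette_xy=pipette_xy))
    return tracks
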