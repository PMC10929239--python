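"""Microglial density and skeleton morphometry.

Cell density is counted from bright somas in a calibrated maximum-intensity
projection of a fixed-tissue field. Single-cell morphology reduces the
binarized cell to its topological skeleton; endpoints (skeleton pixels with
exactly one 8-neighbor) count the process tips, and total branch length sums
the skeleton's step lengths (1 px orthogonal, √2 px diagonal) scaled to µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize

from .imaging import ImageStack, max_project_z

__all__ = [
    "FieldCount",
    "SkeletonMetrics",
    "count_cells",
    "skeletonize_cell",
    "field_morphology",
    "skeleton_endpoints",
    "skeleton_length_px",
]

# Field geometry used throughout: 284 × 284 µm × 20 µm deep.
DEFAULT_FIELD_DEPTH_UM = 20.0
MIN_CELL_AREA_PX = 50


@dataclass(frozen=True)
class FieldCount:
    n_cells: int
    field_volume_um3: float
    density_per_mm3: float


@dataclass(frozen=True)
class SkeletonMetrics:
    """Endpoint count and total branch length (µm) of one cell's skeleton."""

    endpoints: int
    total_branch_length_um: float
    skeleton_px: int
    area_px: int = 0
    cell_id: int = 0


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def skeleton_endpoints(skel: np.ndarray) -> int:
    """Skeleton pixels with exactly one 8-neighbor; an isolated pixel counts as one."""
    skel = np.asarray(skel, bool)
    nbr = ndi.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")
    if skel.sum() == 1:
        return 1
    return int(np.count_nonzero(skel & (nbr == 1)))


def skeleton_length_px(skel: np.ndarray) -> float:
    """Total skeleton length in pixel units.

    Sums unit steps between orthogonally adjacent skeleton pixels and √2 steps
    between diagonally adjacent ones, skipping diagonals that are shortcuts
    across an existing orthogonal path (both pixels sharing an orthogonal
    skeleton neighbor), which would otherwise double-count corners.
    """
    skel = np.asarray(skel, bool)
    ys, xs = np.nonzero(skel)
    pix = set(zip(ys.tolist(), xs.tolist()))
    length = 0.0
    for y, x in pix:
        # orthogonal: count (E, S) only, so each pair is seen once
        for dy, dx in ((0, 1), (1, 0)):
            if (y + dy, x + dx) in pix:
                length += 1.0
        # diagonal: count (SE, SW) only
        for dy, dx in ((1, 1), (1, -1)):
            q = (y + dy, x + dx)
            if q not in pix:
                continue
            # redundant if the two corner cells are both skeleton (a filled 2x2
            # corner already connected through orthogonal steps)
            c1 = (y, x + dx) in pix
            c2 = (y + dy, x) in pix
            if c1 or c2:
                continue
            length += math.sqrt(2.0)
    return length


def skeletonize_cell(cell_mask: np.ndarray, pixel_size: float) -> SkeletonMetrics:
    """Skeletonize one binary cell mask and measure endpoints and branch length."""
    mask = np.asarray(cell_mask, bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    skel = skeletonize(mask)
    if not skel.any():  # tiny masks can skeletonize to nothing; keep the centroid
        skel = np.zeros_like(mask)
        ys, xs = np.nonzero(mask)
        skel[int(round(ys.mean())), int(round(xs.mean()))] = True
    return SkeletonMetrics(
        endpoints=skeleton_endpoints(skel),
        total_branch_length_um=skeleton_length_px(skel) * pixel_size,
        skeleton_px=int(skel.sum()),
        area_px=int(mask.sum()),
    )


def count_cells(
    projection: ImageStack,
    soma_threshold: float | None = None,
    min_soma_area_px: int = 20,
    field_depth_um: float = DEFAULT_FIELD_DEPTH_UM,
) -> FieldCount:
    """Count bright somas in a single projected field and convert to cells/mm³.

    Somas are segmented as blobs above ``soma_threshold`` (Otsu of the
    above-background pixels when not given — somas are rendered/stained brighter
    than processes) and filtered by ``min_soma_area_px``.
    """
    img = (max_project_z(projection) if "Z" in projection.axes else projection).frames_2d()[0].astype(float)
    if soma_threshold is None:
        if np.ptp(img) == 0:
            n = 0
            return _field_count(n, img.shape, projection.pixel_size, field_depth_um)
        fg_thr = threshold_otsu(img)
        fg = img[img > fg_thr]
        # second Otsu separates soma level from process level when both present
        soma_threshold = threshold_otsu(fg) if fg.size and np.ptp(fg) > 0 else fg_thr
    lbl = label(img > soma_threshold)
    n = sum(1 for r in regionprops(lbl) if r.area >= min_soma_area_px)
    return _field_count(n, img.shape, projection.pixel_size, field_depth_um)


def _field_count(n: int, shape: tuple[int, int], pixel_size: float, depth_um: float) -> FieldCount:
    h, w = shape
    vol_um3 = h * pixel_size * w * pixel_size * depth_um
    return FieldCount(n_cells=n, field_volume_um3=vol_um3, density_per_mm3=n / (vol_um3 * 1e-9))


def _split_by_markers(fg: np.ndarray, lbl: np.ndarray, markers_xy) -> np.ndarray:
    """Watershed-split components containing more than one soma marker."""
    from skimage.segmentation import watershed

    per_comp: dict[int, list[tuple[int, int]]] = {}
    for x, y in markers_xy:
        r, c = int(round(y)), int(round(x))
        comp = int(lbl[r, c])
        if comp:
            per_comp.setdefault(comp, []).append((r, c))
    out = lbl.copy()
    next_label = int(lbl.max()) + 1
    for comp, pts in per_comp.items():
        if len(pts) < 2:
            continue
        region = lbl == comp
        seeds = np.zeros_like(lbl)
        for i, (r, c) in enumerate(pts):
            seeds[r, c] = i + 1
        dist = ndi.distance_transform_edt(region)
        ws = watershed(-dist, seeds, mask=region)
        for i in range(1, len(pts) + 1):
            out[ws == i] = next_label
            next_label += 1
    return out


def match_cells_by_position(
    projection: ImageStack,
    cells: list[SkeletonMetrics],
    positions_xy: list[tuple[float, float]],
    threshold: float | None = None,
) -> list[SkeletonMetrics | None]:
    """Pair per-component metrics with known cell positions (e.g. planted somas).

    Re-labels the thresholded projection exactly as :func:`field_morphology`
    does and looks up the component under each (x, y) position; None where no
    component covers the position.
    """
    img = (max_project_z(projection) if "Z" in projection.axes else projection).frames_2d()[0].astype(float)
    if threshold is None:
        threshold = threshold_otsu(img)
    lbl = label(img > threshold)
    by_id = {c.cell_id: c for c in cells}
    out = []
    for x, y in positions_xy:
        out.append(by_id.get(int(lbl[int(round(y)), int(round(x))])))
    return out


def field_morphology(
    projection: ImageStack,
    threshold: float | None = None,
    min_area_px: int = MIN_CELL_AREA_PX,
    soma_markers: list[tuple[float, float]] | None = None,
) -> list[SkeletonMetrics]:
    """Binarize a field, label connected cells, and skeletonize each.

    Components smaller than ``min_area_px`` (debris, isolated pixels) are
    dropped before per-cell statistics. When ``soma_markers`` (x, y positions)
    are given, a component containing more than one marker is split by
    watershed on its distance transform seeded at the markers; otherwise
    touching cells are treated as one component.
    """
    img = (max_project_z(projection) if "Z" in projection.axes else projection).frames_2d()[0].astype(float)
    if threshold is None:
        if np.ptp(img) == 0:
            return []
        threshold = threshold_otsu(img)
    fg = img > threshold
    lbl = label(fg)
    if soma_markers:
        lbl = _split_by_markers(fg, lbl, soma_markers)
    out = []
    for r in regionprops(lbl):
        if r.area < min_area_px:
            continue
        m = skeletonize_cell(lbl == r.label, projection.pixel_size)
        out.append(
            SkeletonMetrics(
                endpoints=m.endpoints,
                total_branch_length_um=m.total_branch_length_um,
                skeleton_px=m.skeleton_px,
                area_px=int(r.area),
                cell_id=int(r.label),
            )
        )
    return out
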