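"""Synthetic fluorescence time-lapses with exact ground truth.

Every analysis stage in this package has a matching generator here that renders
a calibrated image stack *and* records the programmed truth (pixel change
counts, tip tracks, coverage schedule, planted cells, intensity split), so the
whole pipeline can be validated by round-trip recovery instead of against
microscope data. Default geometry mirrors typical ex-vivo confocal acquisition:
1024×1024 fields every 20 s for motility/chemotaxis, 2048×2048 every 15 min for
engulfment, and 284 µm-wide fixed-tissue fields for density/morphology. The
pixel pitch (µm/px) is derived from the 284 µm field width at the stated pixel
counts and is fully configurable.

All stochastic draws come from one ``numpy`` Generator seeded by the config:
identical (config, seed) yields bit-identical stacks and truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .chemotaxis import ProcessTrack
from .imaging import ImageStack
from .motility import ChangeCounts

__all__ = [
    "SimConfig",
    "CellModel",
    "GroundTruth",
    "simulate_baseline_timelapse",
    "simulate_chemotaxis",
    "simulate_abeta_engulfment",
    "simulate_field",
    "simulate_intensity_image",
    "write_ground_truth",
    "read_ground_truth",
]

# pixel pitch inferred from a 284 µm field at 1024 and 2048 px
PIXEL_SIZE_1024 = 284.0 / 1024.0  # ≈ 0.277 µm/px
PIXEL_SIZE_2048 = 284.0 / 2048.0  # ≈ 0.139 µm/px


@dataclass(frozen=True)
class SimConfig:
    """Acquisition geometry and rendering parameters shared by all simulators."""

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = PIXEL_SIZE_1024  # µm/px
    frame_interval: float = 20.0  # s
    n_frames: int = 61  # 20 min at 20 s
    seed: int = 0
    noise_sigma: float = 0.0  # additive Gaussian, 8-bit-like a.u.
    background_level: float = 10.0
    foreground_level: float = 200.0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class CellModel:
    """Generative stand-in for a ramified microglia: a soma disk plus branch polylines."""

    soma_center: tuple[float, float]  # (x, y) px
    soma_radius: float  # px
    branches: tuple[tuple[tuple[float, float], ...], ...]  # polylines, (x, y) px

    @property
    def branch_count(self) -> int:
        return len(self.branches)

    def branch_length_um(self, pixel_size: float) -> float:
        total = 0.0
        for poly in self.branches:
            for (x0, y0), (x1, y1) in zip(poly, poly[1:]):
                total += math.hypot(x1 - x0, y1 - y0)
        return total * pixel_size


@dataclass
class GroundTruth:
    """Programmed parameters recorded by a simulator, for round-trip validation."""

    per_pair_change_counts: list[ChangeCounts] = field(default_factory=list)
    tip_tracks: list[ProcessTrack] = field(default_factory=list)
    programmed_tip_velocity: float | None = None  # µm/min
    arrival_frames: list[int | None] = field(default_factory=list)
    coverage_schedule: list[tuple[float, float]] = field(default_factory=list)  # (minute, %)
    planted_cell_count: int | None = None
    planted_cell_centers: list[tuple[float, float]] = field(default_factory=list)  # (x, y) px
    planted_endpoint_counts: list[int] = field(default_factory=list)
    planted_branch_lengths_um: list[float] = field(default_factory=list)
    intensity_soma_fraction: float | None = None


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------

def _disk_mask(shape, center_xy, radius) -> np.ndarray:
    m = np.zeros(shape, bool)
    rr, cc = draw_disk((center_xy[1], center_xy[0]), radius, shape=shape)
    m[rr, cc] = True
    return m


def _polyline_mask(shape, polyline_xy, thickness: int = 3) -> np.ndarray:
    m = np.zeros(shape, bool)
    pts = [(int(round(y)), int(round(x))) for x, y in polyline_xy]
    for (r0, c0), (r1, c1) in zip(pts, pts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        m[rr[ok], cc[ok]] = True
    if thickness > 1:
        m = ndi.binary_dilation(m, iterations=(thickness - 1) // 2 + (thickness - 1) % 2)
    return m


def _render_frames(masks: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    frames = cfg.background_level + (cfg.foreground_level - cfg.background_level) * masks.astype(np.float32)
    if cfg.noise_sigma > 0:
        frames = frames + rng.normal(0.0, cfg.noise_sigma, frames.shape).astype(np.float32)
    return frames.astype(np.float32)


def _random_cell(rng, shape, center_xy=None, soma_radius=6.0, n_branches=5,
                 branch_len_px=(40.0, 70.0), angle_quantize_deg=None) -> CellModel:
    h, w = shape
    if center_xy is None:
        center_xy = (w / 2.0, h / 2.0)
    cx, cy = center_xy
    if angle_quantize_deg:
        # branches along distinct canonical directions: rasterized (chain-code)
        # length then equals geometric length, so planted truth is exact
        n_dirs = int(round(360.0 / angle_quantize_deg))
        if n_branches > n_dirs:
            raise ValueError(f"at most {n_dirs} branches at {angle_quantize_deg} deg quantization")
        dirs = rng.choice(n_dirs, size=n_branches, replace=False)
        angles = np.sort(dirs) * math.radians(angle_quantize_deg)
    else:
        base = rng.uniform(0, 2 * math.pi)
        angles = base + np.arange(n_branches) * (2 * math.pi / n_branches)
        angles = angles + rng.uniform(-0.15, 0.15, n_branches)  # keep tips well separated
    branches = []
    for a in angles:
        L = rng.uniform(*branch_len_px)
        tip = (cx + L * math.cos(a), cy + L * math.sin(a))
        branches.append(((cx, cy), tip))
    return CellModel(soma_center=(cx, cy), soma_radius=soma_radius, branches=tuple(branches))


def _render_cell(shape, cell: CellModel, branch_thickness: int = 3) -> np.ndarray:
    m = _disk_mask(shape, cell.soma_center, cell.soma_radius)
    for poly in cell.branches:
        m |= _polyline_mask(shape, poly, thickness=branch_thickness)
    return m


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_baseline_timelapse(cfg: SimConfig, turnover_rate: float) -> tuple[ImageStack, GroundTruth]:
    """Spontaneous surveillance: a ramified cell whose margin pixels turn over.

    Per frame pair, approximately ``turnover_rate`` · (cell area) pixels flip:
    half are added on the cell's outer margin (process extension), half removed
    from it (retraction). The exact extend/retract/stable counts of every pair
    are recorded in the ground truth; at ``noise_sigma = 0`` the rendered frames
    binarize back to the underlying masks exactly.
    """
    if not 0 <= turnover_rate < 1:
        raise ValueError("turnover_rate must be in [0, 1)")
    rng = cfg.rng()
    shape = cfg.image_shape
    cell = _random_cell(rng, shape)
    mask = _render_cell(shape, cell)
    masks = [mask]
    truth = GroundTruth()
    for _ in range(cfg.n_frames - 1):
        prev = masks[-1]
        area = int(prev.sum())
        k = int(round(turnover_rate * area / 2.0))
        addable = ndi.binary_dilation(prev) & ~prev
        removable = prev & ~ndi.binary_erosion(prev)
        add_idx = np.flatnonzero(addable.ravel())
        rem_idx = np.flatnonzero(removable.ravel())
        k_add = min(k, add_idx.size)
        k_rem = min(k, rem_idx.size)
        nxt = prev.copy().ravel()
        if k_add:
            nxt[rng.choice(add_idx, size=k_add, replace=False)] = True
        if k_rem:
            nxt[rng.choice(rem_idx, size=k_rem, replace=False)] = False
        nxt = nxt.reshape(shape)
        truth.per_pair_change_counts.append(
            ChangeCounts(
                extend=int(np.count_nonzero(nxt & ~prev)),
                retract=int(np.count_nonzero(prev & ~nxt)),
                stable=int(np.count_nonzero(prev & nxt)),
            )
        )
        masks.append(nxt)
    frames = _render_frames(np.stack(masks), cfg, rng)
    stack = ImageStack(frames, "TYX", cfg.pixel_size, cfg.frame_interval)
    return stack, truth


def simulate_chemotaxis(
    cfg: SimConfig,
    tip_velocity: float,
    pipette_xy: tuple[float, float] | None = None,
    n_processes: int = 3,
    jitter_sigma_px: float = 0.0,
    start_distance_um: float = 30.0,
    capture_radius_um: float = 2.0,
    tip_radius_px: float = 2.0,
) -> tuple[ImageStack, GroundTruth]:
    """Directed process extension toward an ATP-containing pipette.

    ``n_processes`` tips start ``start_distance_um`` from the pipette at spread
    angles and advance toward it at ``tip_velocity`` µm/min (converted to
    px/frame via the calibration), with optional isotropic Gaussian jitter. A
    tip freezes once it comes within ``capture_radius_um`` of the pipette
    (arrival). True float-precision tracks and arrival frames are recorded.
    """
    if tip_velocity < 0:
        raise ValueError("tip_velocity must be >= 0")
    if n_processes < 1:
        raise ValueError("n_processes must be >= 1")
    h, w = cfg.image_shape
    if pipette_xy is None:
        pipette_xy = (w / 2.0, h / 2.0)
    px, py = pipette_xy
    if not (0 <= px < w and 0 <= py < h):
        raise ValueError("pipette must lie inside the field")
    rng = cfg.rng()
    step_px = tip_velocity * (cfg.frame_interval / 60.0) / cfg.pixel_size
    start_px = start_distance_um / cfg.pixel_size
    capture_px = capture_radius_um / cfg.pixel_size
    base = rng.uniform(0, 2 * math.pi)
    angles = base + np.arange(n_processes) * (2 * math.pi / max(n_processes, 1))
    positions = [
        np.array([px + start_px * math.cos(a), py + start_px * math.sin(a)]) for a in angles
    ]
    tracks_pts = [[(0, float(p[0]), float(p[1]))] for p in positions]
    arrivals: list[int | None] = [
        0 if np.hypot(*(p - (px, py))) <= capture_px else None for p in positions
    ]
    frames = np.zeros((cfg.n_frames, h, w), bool)
    for i, p in enumerate(positions):
        frames[0] |= _disk_mask((h, w), p, tip_radius_px)
    for t in range(1, cfg.n_frames):
        for i, p in enumerate(positions):
            if arrivals[i] is None:
                d = np.array([px, py]) - p
                dist = np.hypot(*d)
                if dist > 1e-9 and step_px > 0:
                    move = d / dist * min(step_px, dist)
                    p = p + move
                if jitter_sigma_px > 0:
                    p = p + rng.normal(0.0, jitter_sigma_px, 2)
                p[0] = min(max(p[0], 0.0), w - 1.0)
                p[1] = min(max(p[1], 0.0), h - 1.0)
                positions[i] = p
                if np.hypot(p[0] - px, p[1] - py) <= capture_px:
                    arrivals[i] = t
            tracks_pts[i].append((t, float(positions[i][0]), float(positions[i][1])))
            frames[t] |= _disk_mask((h, w), positions[i], tip_radius_px)
    truth = GroundTruth(
        tip_tracks=[
            ProcessTrack(points=tuple(pts), track_id=f"tip{i}", pipette_xy=(px, py))
            for i, pts in enumerate(tracks_pts)
        ],
        programmed_tip_velocity=tip_velocity,
        arrival_frames=arrivals,
    )
    data = _render_frames(frames, cfg, rng)
    stack = ImageStack(data, "TYX", cfg.pixel_size, cfg.frame_interval)
    return stack, truth


def default_engulfment_config(seed: int = 0, **overrides) -> SimConfig:
    """Engulfment-geometry config: 2048² field imaged every 15 min for 2 h (9 frames)."""
    kw = dict(
        image_shape=(2048, 2048),
        pixel_size=PIXEL_SIZE_2048,
        frame_interval=900.0,
        n_frames=9,
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def simulate_abeta_engulfment(
    cfg: SimConfig,
    schedule: list[tuple[float, float]],
    deposit_radius_px: float | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """Two-channel engulfment: a fixed Aβ deposit progressively covered by microglia.

    ``schedule`` lists (minute, percent-coverage) control points; coverage at
    each rendered frame is linearly interpolated between them. Microglial
    pixels sweep across the deposit from one side (a growing covered front plus
    an approach process from the field edge), so the covered sets are nested and
    a monotone schedule yields a monotone series. The truth records the exact
    rendered percent per frame.
    """
    if not schedule:
        raise ValueError("schedule must contain at least one (minute, percent) point")
    minutes = [m for m, _ in schedule]
    pcts = [p for _, p in schedule]
    if any(b <= a for a, b in zip(minutes, minutes[1:])):
        raise ValueError("schedule minutes must be strictly ascending")
    if any(not 0 <= p <= 100 for p in pcts):
        raise ValueError("schedule percents must be in [0, 100]")
    rng = cfg.rng()
    h, w = cfg.image_shape
    if deposit_radius_px is None:
        deposit_radius_px = min(h, w) / 8.0
    center = (w / 2.0, h / 2.0)
    deposit = _disk_mask((h, w), center, deposit_radius_px)
    # covered front sweeps left→right: order deposit pixels by column, then row
    rr, cc = np.nonzero(deposit)
    order = np.lexsort((rr, cc))
    rr, cc = rr[order], cc[order]
    area = rr.size
    # approach process from the left edge, stopping short of the deposit
    strip = np.zeros((h, w), bool)
    y0 = int(center[1])
    x_stop = int(center[0] - deposit_radius_px - 4)
    strip[y0 - 2 : y0 + 3, 0 : max(x_stop, 0)] = True
    dt_min = cfg.frame_interval / 60.0
    glia = np.zeros((cfg.n_frames, h, w), bool)
    abeta = np.zeros((cfg.n_frames, h, w), bool)
    rendered: list[tuple[float, float]] = []
    for t in range(cfg.n_frames):
        minute = t * dt_min
        pct = float(np.interp(minute, minutes, pcts))
        k = int(round(pct / 100.0 * area))
        g = strip.copy()
        g[rr[:k], cc[:k]] = True
        glia[t] = g
        abeta[t] = deposit
        rendered.append((minute, 100.0 * k / area))
    data = np.stack([glia, abeta], axis=1)  # T, C, Y, X
    frames = _render_frames(data, cfg, rng)
    stack = ImageStack(
        frames, "TCYX", cfg.pixel_size, cfg.frame_interval, channel_names=("microglia", "abeta")
    )
    return stack, GroundTruth(coverage_schedule=rendered)


def simulate_field(
    cfg: SimConfig,
    n_cells: int,
    soma_radius_px: float = 3.0,
    n_branches: tuple[int, int] = (4, 6),
    branch_len_um: tuple[float, float] = (12.0, 20.0),
    branch_thickness: int = 3,
    soma_level: float | None = None,
    angle_quantize_deg: float | None = 45.0,
    max_tries: int = 2000,
) -> tuple[ImageStack, GroundTruth]:
    """A single fixed-tissue field of ramified cells for density/morphology.

    Cells are placed with enough separation that their branch envelopes cannot
    touch; somas render brighter than processes so soma counting can segment
    them. The truth records the planted cell count and, per cell, the branch
    (endpoint) count and total geometric branch length in µm, measured from the
    soma center along each planted polyline.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = cfg.rng()
    h, w = cfg.image_shape
    max_branch_px = branch_len_um[1] / cfg.pixel_size
    margin = max_branch_px + soma_radius_px + 3
    min_sep = 2 * margin + 4
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_cells} cells with separation {min_sep:.0f} px in {h}x{w}"
            )
        c = (rng.uniform(margin, w - margin), rng.uniform(margin, h - margin))
        if all(math.hypot(c[0] - ox, c[1] - oy) >= min_sep for ox, oy in centers):
            centers.append(c)
    if soma_level is None:
        soma_level = cfg.foreground_level
    process_level = cfg.background_level + 0.6 * (cfg.foreground_level - cfg.background_level)
    img = np.full((h, w), cfg.background_level, np.float32)
    truth = GroundTruth(planted_cell_count=n_cells)
    for c in centers:
        nb = int(rng.integers(n_branches[0], n_branches[1] + 1))
        cell = _random_cell(
            rng,
            (h, w),
            center_xy=c,
            soma_radius=soma_radius_px,
            n_branches=nb,
            branch_len_px=(branch_len_um[0] / cfg.pixel_size, branch_len_um[1] / cfg.pixel_size),
            angle_quantize_deg=angle_quantize_deg,
        )
        proc_mask = np.zeros((h, w), bool)
        for poly in cell.branches:
            # draw the centerline 0.5 px past the planted tip: the medial-axis
            # skeleton of a 3 px-wide bar retracts ~1 px from each end, and this
            # centers the measured length on the planted geometric length
            (x0, y0), (x1, y1) = poly[0], poly[-1]
            L = math.hypot(x1 - x0, y1 - y0)
            f = (L + 0.5) / L
            drawn = ((x0, y0), (x0 + (x1 - x0) * f, y0 + (y1 - y0) * f))
            proc_mask |= _polyline_mask((h, w), drawn, thickness=branch_thickness)
        soma_mask = _disk_mask((h, w), cell.soma_center, cell.soma_radius)
        img[proc_mask] = process_level
        img[soma_mask] = soma_level
        truth.planted_cell_centers.append(c)
        truth.planted_endpoint_counts.append(cell.branch_count)
        truth.planted_branch_lengths_um.append(cell.branch_length_um(cfg.pixel_size))
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape).astype(np.float32)
    stack = ImageStack(img.astype(np.float32), "YX", cfg.pixel_size)
    return stack, truth


def simulate_intensity_image(
    cfg: SimConfig,
    soma_fraction: float,
    n_cells: int = 4,
    total_intensity: float = 1.0e5,
    soma_radius_px: float = 8.0,
) -> tuple[ImageStack, list, GroundTruth]:
    """Receptor-staining field whose signal is split between somas and processes.

    The integrated intensity inside the soma masks is exactly
    ``soma_fraction`` · ``total_intensity``; the rest lies on process polylines
    outside the somas. Returns the image, the soma masks, and the truth.
    Backgrounds and noise default to zero so the partition is exact; any
    non-zero background is counted as process signal by the analysis.
    """
    if not 0 <= soma_fraction <= 1:
        raise ValueError("soma_fraction must be in [0, 1]")
    rng = cfg.rng()
    h, w = cfg.image_shape
    soma = np.zeros((h, w), bool)
    proc = np.zeros((h, w), bool)
    margin = soma_radius_px + 60
    centers = []
    for _ in range(n_cells):
        for _try in range(200):
            c = (rng.uniform(margin, w - margin), rng.uniform(margin, h - margin))
            if all(math.hypot(c[0] - ox, c[1] - oy) > 4 * margin / n_cells + 2 * soma_radius_px for ox, oy in centers):
                break
        centers.append(c)
        soma |= _disk_mask((h, w), c, soma_radius_px)
        cell = _random_cell(rng, (h, w), center_xy=c, soma_radius=soma_radius_px,
                            n_branches=5, branch_len_px=(30.0, 50.0))
        for poly in cell.branches:
            proc |= _polyline_mask((h, w), poly, thickness=3)
    proc &= ~soma
    img = np.zeros((h, w), np.float64)
    if soma.any() and soma_fraction > 0:
        img[soma] = soma_fraction * total_intensity / soma.sum()
    if proc.any() and soma_fraction < 1:
        img[proc] = (1.0 - soma_fraction) * total_intensity / proc.sum()
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    from .imaging import RoiMask

    stack = ImageStack(img.astype(np.float32), "YX", cfg.pixel_size)
    masks = [RoiMask(mask=soma, label="somas")]
    return stack, masks, GroundTruth(intensity_soma_fraction=soma_fraction)


# ---------------------------------------------------------------------------
# ground-truth JSON sidecar
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    d = {
        "per_pair_change_counts": [dataclasses.asdict(c) for c in truth.per_pair_change_counts],
        "tip_tracks": [
            {"track_id": t.track_id, "cell_id": t.cell_id, "pipette_xy": t.pipette_xy, "points": list(t.points)}
            for t in truth.tip_tracks
        ],
        "programmed_tip_velocity": truth.programmed_tip_velocity,
        "arrival_frames": truth.arrival_frames,
        "coverage_schedule": truth.coverage_schedule,
        "planted_cell_count": truth.planted_cell_count,
        "planted_cell_centers": truth.planted_cell_centers,
        "planted_endpoint_counts": truth.planted_endpoint_counts,
        "planted_branch_lengths_um": truth.planted_branch_lengths_um,
        "intensity_soma_fraction": truth.intensity_soma_fraction,
    }
    Path(path).write_text(json.dumps(d, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        per_pair_change_counts=[ChangeCounts(**c) for c in d["per_pair_change_counts"]],
        tip_tracks=[
            ProcessTrack(
                points=tuple((int(f), float(x), float(y)) for f, x, y in t["points"]),
                track_id=t["track_id"],
                cell_id=t["cell_id"],
                pipette_xy=tuple(t["pipette_xy"]) if t["pipette_xy"] else None,
            )
            for t in d["tip_tracks"]
        ],
        programmed_tip_velocity=d["programmed_tip_velocity"],
        arrival_frames=d["arrival_frames"],
        coverage_schedule=[tuple(p) for p in d["coverage_schedule"]],
        planted_cell_count=d["planted_cell_count"],
        planted_cell_centers=[tuple(c) for c in d.get("planted_cell_centers", [])],
        planted_endpoint_counts=d["planted_endpoint_counts"],
        planted_branch_lengths_um=d["planted_branch_lengths_um"],
        intensity_soma_fraction=d["intensity_soma_fraction"],
    )
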