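"""Surveillance motility: binarization, frame-pair pixel turnover, motility index.

A binarized microglia time-lapse is compared frame to frame: pixels present only
in the later frame are *extending* (green), pixels present only in the earlier
frame are *retracting* (red), pixels present in both are *stable* (yellow). The
motility index of a frame pair is (extending + retracting) / stable, and a
time-lapse is summarized by the mean index over its defined pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .imaging import ImageStack, RoiMask, apply_roi, max_project_z, register_translation

__all__ = [
    "BinaryTimelapse",
    "ChangeCounts",
    "MotilityResult",
    "binarize",
    "classify_pixel_changes",
    "motility_index",
    "timelapse_motility",
]


@dataclass(frozen=True)
class ChangeCounts:
    """Pixel tallies for one frame pair: extend (green), retract (red), stable (yellow)."""

    extend: int
    retract: int
    stable: int

    def __post_init__(self):
        if min(self.extend, self.retract, self.stable) < 0:
            raise ValueError("pixel counts must be non-negative")

    @property
    def area_before(self) -> int:
        return self.retract + self.stable

    @property
    def area_after(self) -> int:
        return self.extend + self.stable


@dataclass(frozen=True)
class BinaryTimelapse:
    masks: np.ndarray  # bool, (T, Y, X)
    threshold_method: str
    threshold_values: tuple[float, ...]

    def __post_init__(self):
        m = np.asarray(self.masks, bool)
        object.__setattr__(self, "masks", m)
        if m.ndim != 3:
            raise ValueError("masks must be (T, Y, X)")


@dataclass(frozen=True)
class MotilityResult:
    per_pair_index: tuple[float, ...]  # nan where the pair was undefined (stable = 0)
    mean_index: float
    n_pairs: int
    excluded_pairs: int
    threshold_method: str = ""
    threshold_values: tuple[float, ...] = ()

    @property
    def valid(self) -> bool:
        return self.n_pairs > 0


def binarize(stack: ImageStack, method: str = "otsu_mean", threshold: float | None = None) -> BinaryTimelapse:
    """Threshold a single-channel time-lapse into foreground masks.

    ``method``:

    - ``fixed``: the supplied ``threshold`` applied to every frame;
    - ``otsu_global``: Otsu on the pooled pixel distribution of all frames;
    - ``otsu_mean``: Otsu on the temporal mean image, applied fixed to all
      frames (default — avoids frame-to-frame threshold flicker);
    - ``otsu_per_frame``: Otsu recomputed per frame.
    """
    if "C" in stack.axes:
        raise ValueError("binarize expects a single-channel stack")
    frames = (max_project_z(stack) if "Z" in stack.axes else stack).frames_2d().astype(float)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = [float(threshold)] * len(frames)
    elif method == "otsu_global":
        t = _otsu_or_min(frames)
        thr = [t] * len(frames)
    elif method == "otsu_mean":
        t = _otsu_or_min(frames.mean(axis=0))
        thr = [t] * len(frames)
    elif method == "otsu_per_frame":
        thr = [_otsu_or_min(f) for f in frames]
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    masks = np.stack([f > t for f, t in zip(frames, thr)])
    if not masks.any():
        warnings.warn("binarize: empty foreground in every frame", stacklevel=2)
    return BinaryTimelapse(masks=masks, threshold_method=method, threshold_values=tuple(thr))


def _otsu_or_min(img: np.ndarray) -> float:
    if np.ptp(img) == 0:
        return float(img.min()) - 1.0  # constant image: everything is foreground
    return float(threshold_otsu(img))


def classify_pixel_changes(mask_t: np.ndarray, mask_t1: np.ndarray) -> ChangeCounts:
    """Count extending / retracting / stable pixels between two binary frames."""
    a = np.asarray(mask_t, bool)
    b = np.asarray(mask_t1, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    stable = int(np.count_nonzero(a & b))
    extend = int(np.count_nonzero(b & ~a))
    retract = int(np.count_nonzero(a & ~b))
    return ChangeCounts(extend=extend, retract=retract, stable=stable)


def motility_index(counts: ChangeCounts) -> float:
    """(extend + retract) / stable; NaN (excluded pair) when stable = 0."""
    if counts.stable == 0:
        return math.nan
    return (counts.extend + counts.retract) / counts.stable


def _summarize(indices: list[float], method: str = "", thr: tuple[float, ...] = ()) -> MotilityResult:
    defined = [v for v in indices if not math.isnan(v)]
    mean = float(np.mean(defined)) if defined else math.nan
    return MotilityResult(
        per_pair_index=tuple(indices),
        mean_index=mean,
        n_pairs=len(defined),
        excluded_pairs=len(indices) - len(defined),
        threshold_method=method,
        threshold_values=thr,
    )


def timelapse_motility(
    stack: ImageStack,
    roi: RoiMask | None = None,
    threshold_method: str = "otsu_mean",
    threshold: float | None = None,
    register: bool = True,
    reference: int = 0,
) -> MotilityResult:
    """Full motility pipeline: register → ROI crop → binarize → per-pair index → mean.

    A 20-min lapse at 20-s intervals (61 frames) yields 60 frame pairs. Pairs with
    no stable pixels are excluded from the mean and reported in ``excluded_pairs``.
    """
    work = max_project_z(stack) if "Z" in stack.axes else stack
    if work.n_frames < 2:
        raise ValueError("motility requires at least 2 time points")
    if register:
        # pairwise mode corrects abrupt field drift without "undoing" the slow
        # net remodeling of the cell itself
        work, _ = register_translation(work, reference=reference, mode="pairwise")
    if roi is not None:
        work = apply_roi(work, roi)
    binary = binarize(work, method=threshold_method, threshold=threshold)
    indices = [
        motility_index(classify_pixel_changes(binary.masks[t], binary.masks[t + 1]))
        for t in range(len(binary.masks) - 1)
    ]
    return _summarize(indices, binary.threshold_method, binary.threshold_values)
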