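"""Calibrated image stacks: TIFF I/O, z-projection, drift registration, ROI masking.

The in-memory container is :class:`ImageStack`, a thin calibrated wrapper around a
numpy array whose axes follow the ImageJ hyperstack convention ``T, Z, C, Y, X``
(slowest to fastest; absent axes are simply dropped from the ``axes`` string).
All physical conversions go through ``pixel_size`` (µm/px) and ``frame_interval``
(seconds between time points).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
import tifffile
from skimage.registration import phase_cross_correlation

__all__ = [
    "ImageStack",
    "RoiMask",
    "CalibrationError",
    "read_stack",
    "write_stack",
    "max_project_z",
    "register_translation",
    "apply_roi",
    "read_mask",
    "write_mask",
]

_AXIS_ORDER = "TZCYX"


class CalibrationError(ValueError):
    """Raised when an image file carries no pixel size / interval and none is supplied."""


@dataclass(frozen=True)
class ImageStack:
    """A fluorescence image stack with spatial and temporal calibration.

    Parameters
    ----------
    data:
        Intensity array. Axis semantics are given by ``axes``.
    axes:
        Subsequence of ``"TZCYX"`` (e.g. ``"TYX"``, ``"TCYX"``); must end in ``YX``.
    pixel_size:
        Lateral pixel pitch in µm/px (> 0).
    frame_interval:
        Seconds between consecutive time points; required when T > 1.
    channel_names:
        Optional labels for the C axis, config order.
    """

    data: np.ndarray
    axes: str
    pixel_size: float
    frame_interval: float | None = None
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self):
        axes = self.axes.upper()
        if axes != self.axes:
            object.__setattr__(self, "axes", axes)
        if not axes.endswith("YX") or any(a not in _AXIS_ORDER for a in axes):
            raise ValueError(f"axes must be an ordered subset of {_AXIS_ORDER} ending in YX, got {axes!r}")
        if [_AXIS_ORDER.index(a) for a in axes] != sorted(_AXIS_ORDER.index(a) for a in axes):
            raise ValueError(f"axes must follow {_AXIS_ORDER} order, got {axes!r}")
        if self.data.ndim != len(axes):
            raise ValueError(f"data has {self.data.ndim} dims but axes is {axes!r}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.n_frames > 1 and (self.frame_interval is None or not self.frame_interval > 0):
            raise CalibrationError("frame_interval must be positive for stacks with T > 1")
        if self.channel_names is not None:
            object.__setattr__(self, "channel_names", tuple(self.channel_names))
            if "C" in axes and len(self.channel_names) != self.axis_len("C"):
                raise ValueError("channel_names length must match C axis")

    # -- axis helpers -------------------------------------------------
    def axis_index(self, axis: str) -> int:
        if axis not in self.axes:
            raise ValueError(f"stack has no {axis!r} axis (axes={self.axes!r})")
        return self.axes.index(axis)

    def axis_len(self, axis: str) -> int:
        return self.data.shape[self.axis_index(axis)]

    @property
    def n_frames(self) -> int:
        return self.axis_len("T") if "T" in self.axes else 1

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]

    def channel(self, name_or_index: str | int) -> "ImageStack":
        """Extract one channel as a C-less stack."""
        if isinstance(name_or_index, str):
            if self.channel_names is None or name_or_index not in self.channel_names:
                raise ValueError(f"unknown channel {name_or_index!r}")
            idx = self.channel_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        ci = self.axis_index("C")
        data = np.take(self.data, idx, axis=ci)
        return replace(self, data=data, axes=self.axes.replace("C", ""), channel_names=None)

    def frames_2d(self) -> np.ndarray:
        """View the stack as (T, Y, X); requires no Z or C axis."""
        if "C" in self.axes or "Z" in self.axes:
            raise ValueError("frames_2d requires a single-channel, z-projected stack")
        if "T" in self.axes:
            return self.data
        return self.data[np.newaxis]

    def with_data(self, data: np.ndarray, axes: str | None = None) -> "ImageStack":
        return replace(self, data=data, axes=self.axes if axes is None else axes)


@dataclass(frozen=True)
class RoiMask:
    """Boolean region-of-interest mask, one microglia (or field region) per mask."""

    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise ValueError("RoiMask must be 2-D (Y, X)")
        if not m.any():
            raise ValueError("RoiMask is empty")


# ---------------------------------------------------------------------------
# TIFF I/O (ImageJ dialect)
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an ImageJ-compatible TIFF with pixel size and frame interval metadata."""
    data = stack.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    elif data.dtype == np.bool_:
        data = data.astype(np.uint8)
    meta = {"axes": stack.axes, "unit": "um", "spacing": 1.0}
    if stack.frame_interval is not None:
        meta["finterval"] = float(stack.frame_interval)
    if stack.channel_names is not None:
        meta["channel_names"] = ",".join(stack.channel_names)
    res = 1.0 / stack.pixel_size
    tifffile.imwrite(str(path), data, imagej=True, resolution=(res, res), metadata=meta)


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    axes: str | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a TIFF stack, taking calibration from ImageJ metadata or from overrides.

    Raises :class:`CalibrationError` when no pixel size can be determined.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        file_axes = series.axes
        ij = tif.imagej_metadata or {}
        page0 = tif.pages[0]
        xres = page0.tags.get("XResolution")
    if pixel_size is None:
        if xres is not None:
            num, den = xres.value
            # a bare (1, 1) resolution with no unit is tifffile's placeholder,
            # not a real calibration
            if num and not ((num, den) == (1, 1) and "unit" not in ij):
                pixel_size = den / num
        if pixel_size is None or pixel_size <= 0:
            raise CalibrationError(f"{path}: no pixel size in metadata; pass pixel_size=")
    if frame_interval is None:
        fi = ij.get("finterval")
        frame_interval = float(fi) if fi else None
    if channel_names is None:
        cn = ij.get("channel_names")
        channel_names = tuple(cn.split(",")) if cn else None
    if axes is None:
        # tifffile reports ImageJ axes; map its sample axis away and keep TZCYX subset
        axes = "".join(a for a in file_axes if a in _AXIS_ORDER)
        if len(axes) != data.ndim:
            # squeeze singleton non-spatial axes (e.g. sample axis S)
            keep = [i for i, a in enumerate(file_axes) if a in _AXIS_ORDER]
            data = data.transpose(keep + [i for i in range(data.ndim) if i not in keep])
            data = data.reshape(data.shape[: len(keep)])
    return ImageStack(
        data=data,
        axes=axes,
        pixel_size=float(pixel_size),
        frame_interval=frame_interval,
        channel_names=tuple(channel_names) if channel_names else None,
    )


def write_mask(mask: np.ndarray | RoiMask, path: str | Path) -> None:
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, bool)
    tifffile.imwrite(str(path), m.astype(np.uint8) * 255)


def read_mask(path: str | Path, label: str = "roi") -> RoiMask:
    arr = tifffile.imread(str(path))
    return RoiMask(mask=arr > 0, label=label)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def max_project_z(stack: ImageStack) -> ImageStack:
    """Maximum-intensity projection across the z axis; other axes preserved."""
    zi = stack.axis_index("Z")
    proj = stack.data.max(axis=zi)
    return stack.with_data(proj, stack.axes.replace("Z", ""))


def modal_background(frame: np.ndarray) -> float:
    """Most frequent (rounded) intensity — a robust flat-background estimate."""
    vals, counts = np.unique(np.round(np.asarray(frame, float)), return_counts=True)
    return float(vals[np.argmax(counts)])


def register_translation(
    stack: ImageStack,
    reference: int = 0,
    upsample_factor: int = 1,
    mode: str = "reference",
) -> tuple[ImageStack, np.ndarray]:
    """Stabilize a time-lapse by translation-only phase correlation.

    ``mode="reference"`` aligns every frame directly to the ``reference``
    frame. ``mode="pairwise"`` estimates the shift between consecutive frames
    and applies the accumulated correction; this tracks abrupt field drift
    while leaving slow biological remodeling (which has no frame-to-frame
    offset) untouched. Pixels shifted in from outside the field are filled
    with the modal background so the border does not masquerade as
    extending/retracting structure. Returns the registered stack and the
    applied (dy, dx) shifts, one row per frame.
    """
    if mode not in ("reference", "pairwise"):
        raise ValueError("mode must be 'reference' or 'pairwise'")
    frames = stack.frames_2d()
    T = frames.shape[0]
    if T < 2:
        raise ValueError("registration requires T >= 2")
    ref = frames[reference]
    shifts = np.zeros((T, 2), dtype=float)
    out = np.empty_like(frames, dtype=float)
    cval = modal_background(ref)
    for t in range(T):
        if t == reference:
            out[t] = frames[t]
            continue
        target = frames[t - 1] if mode == "pairwise" and t > 0 else ref
        if np.ptp(frames[t]) == 0 or np.ptp(target) == 0:
            shift = np.zeros(2)  # degenerate constant frame: nothing to align
        else:
            shift, _, _ = phase_cross_correlation(target, frames[t], upsample_factor=upsample_factor)
        if mode == "pairwise" and t > 0:
            shift = shifts[t - 1] + shift  # accumulate frame-to-frame corrections
        shifts[t] = shift
        if np.allclose(shift, np.round(shift)):
            out[t] = ndi.shift(frames[t].astype(float), shift, order=0, cval=cval)
        else:
            out[t] = ndi.shift(frames[t].astype(float), shift, order=1, cval=cval)
    data = out if "T" in stack.axes else out[0]
    return stack.with_data(data), shifts


def write_shifts_csv(shifts: np.ndarray, path: str | Path) -> None:
    """Write registration shifts as CSV with columns frame, dy, dx."""
    import pandas as pd

    df = pd.DataFrame(
        {"frame": np.arange(len(shifts)), "dy": shifts[:, 0], "dx": shifts[:, 1]}
    )
    df.to_csv(path, index=False)


def apply_roi(stack: ImageStack, roi: RoiMask) -> ImageStack:
    """Zero all pixels outside the ROI, for every frame/plane/channel."""
    if roi.mask.shape != stack.frame_shape:
        raise ValueError(f"ROI shape {roi.mask.shape} != frame shape {stack.frame_shape}")
    data = np.where(roi.mask, stack.data, 0)
    return stack.with_data(data)
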