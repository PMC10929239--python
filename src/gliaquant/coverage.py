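"""Two-channel Aβ engulfment coverage.

At each time point the microglia and Aβ channels are binarized independently
(separate acquisition channels, no spectral unmixing) and color-coded: yellow =
microglia ∩ Aβ, red = Aβ only. Percent coverage is 100 · yellow / (yellow + red),
i.e. the fraction of the deposit's area overlapped by microglial pixels; note
yellow + red always equals the Aβ mask area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imaging import ImageStack, max_project_z
from .motility import binarize

__all__ = ["CoveragePoint", "CoverageTimeSeries", "coverage_fraction", "coverage_timeseries"]


@dataclass(frozen=True)
class CoveragePoint:
    minute: float
    yellow_px: int
    red_px: int
    percent_coverage: float  # NaN when the Aβ mask is empty


@dataclass(frozen=True)
class CoverageTimeSeries:
    points: tuple[CoveragePoint, ...]
    microglia_threshold: tuple[float, ...] = ()
    abeta_threshold: tuple[float, ...] = ()

    @property
    def minutes(self) -> tuple[float, ...]:
        return tuple(p.minute for p in self.points)

    @property
    def percents(self) -> tuple[float, ...]:
        return tuple(p.percent_coverage for p in self.points)


def coverage_fraction(microglia_mask: np.ndarray, abeta_mask: np.ndarray, minute: float = 0.0) -> CoveragePoint:
    """Overlap of microglia over the Aβ deposit for one time point."""
    g = np.asarray(microglia_mask, bool)
    r = np.asarray(abeta_mask, bool)
    if g.shape != r.shape:
        raise ValueError(f"mask shapes differ: {g.shape} vs {r.shape}")
    yellow = int(np.count_nonzero(g & r))
    red = int(np.count_nonzero(r & ~g))
    total = yellow + red
    pct = 100.0 * yellow / total if total else math.nan
    return CoveragePoint(minute=minute, yellow_px=yellow, red_px=red, percent_coverage=pct)


def coverage_timeseries(
    stack: ImageStack,
    microglia_channel: str | int = "microglia",
    abeta_channel: str | int = "abeta",
    threshold_method: str = "otsu_mean",
    freeze_abeta: bool = False,
) -> CoverageTimeSeries:
    """Percent coverage over a two-channel time-lapse (default 0–120 min by 15).

    ``freeze_abeta=True`` fixes the Aβ mask at t0 (useful when the deposit is
    static and a monotone series is expected); otherwise the deposit is
    re-binarized per time point, allowing diffusion or compaction.
    """
    if "C" not in stack.axes:
        raise ValueError("coverage requires a two-channel stack")
    if stack.n_frames < 2:
        raise ValueError("coverage requires at least 2 time points")
    glia = stack.channel(microglia_channel)
    abeta = stack.channel(abeta_channel)
    if "Z" in stack.axes:
        glia, abeta = max_project_z(glia), max_project_z(abeta)
    bg = binarize(glia, method=threshold_method)
    ba = binarize(abeta, method=threshold_method)
    if not ba.masks[0].any():
        raise ValueError("Aβ channel is empty at t0")
    dt_min = (stack.frame_interval or 0.0) / 60.0
    points = []
    for t in range(stack.n_frames):
        amask = ba.masks[0] if freeze_abeta else ba.masks[t]
        points.append(coverage_fraction(bg.masks[t], amask, minute=t * dt_min))
    return CoverageTimeSeries(
        points=tuple(points),
        microglia_threshold=bg.threshold_values,
        abeta_threshold=ba.threshold_values,
    )
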