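"""Receptor-staining intensity quantification and ΔΔCt qPCR fold change.

The soma/process partition follows the crop-out procedure: total field
intensity is summed, the soma masks are cropped out, and the remainder is
attributed to processes; percent-in-processes = 100 · process / (process + soma).

Relative transcript quantification uses the Livak double-delta-Ct method:
replicate Cq values are averaged per (sample, gene), ΔCt = Cq_target −
Cq_reference per sample, ΔΔCt = group-mean ΔCt minus reference-group-mean ΔCt,
and fold change = 2^(−ΔΔCt), so the reference group (e.g. APOE3) is 1.0 by
construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import ImageStack, RoiMask

__all__ = [
    "IntensityPartition",
    "FoldChangeResult",
    "intensity_partition",
    "total_field_intensity",
    "ddct_fold_change",
    "read_qpcr_csv",
]


@dataclass(frozen=True)
class IntensityPartition:
    total_intensity: float
    soma_intensity: float
    process_intensity: float
    percent_in_processes: float  # NaN when total is zero


@dataclass(frozen=True)
class FoldChangeResult:
    per_sample_dct: pd.DataFrame  # columns: sample_id, group, dct
    ddct: dict[str, float]  # group -> ΔΔCt
    fold_change: dict[str, float]  # group -> 2^(−ΔΔCt)
    reference_group: str


def _image_2d(image: ImageStack) -> np.ndarray:
    if "C" in image.axes:
        raise ValueError("expected a single-channel image")
    from .imaging import max_project_z

    img = max_project_z(image) if "Z" in image.axes else image
    return img.frames_2d()[0].astype(float)


def total_field_intensity(image: ImageStack, background: float = 0.0) -> tuple[float, float]:
    """Sum and mean pixel intensity (a.u.) over the whole field.

    ``background`` is an optional constant subtracted per pixel with clamping at
    zero; the default reports raw arbitrary units.
    """
    img = _image_2d(image)
    if background:
        img = np.clip(img - background, 0, None)
    return float(img.sum()), float(img.mean())


def intensity_partition(image: ImageStack, soma_masks: list[RoiMask]) -> IntensityPartition:
    """Split total field intensity into soma vs process compartments."""
    img = _image_2d(image)
    union = np.zeros(img.shape, bool)
    for roi in soma_masks:
        if roi.mask.shape != img.shape:
            raise ValueError("soma mask shape does not match image")
        union |= roi.mask
    total = float(img.sum())
    soma = float(img[union].sum())
    process = total - soma
    pct = 100.0 * process / total if total else math.nan
    return IntensityPartition(
        total_intensity=total,
        soma_intensity=soma,
        process_intensity=process,
        percent_in_processes=pct,
    )


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    """Load a qPCR table with columns sample_id, group, gene, cq.

    ``gene`` is either the target transcript name or the reference
    (housekeeping) gene; replicate rows share (sample_id, gene).
    """
    df = pd.read_csv(path)
    required = {"sample_id", "group", "gene", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    return df


def ddct_fold_change(
    table: pd.DataFrame,
    reference_group: str,
    target_gene: str = "target",
    reference_gene: str = "reference",
) -> FoldChangeResult:
    """Double-delta-Ct relative quantification against ``reference_group``.

    Samples lacking the reference gene are excluded with a warning.
    """
    df = table.copy()
    if (df["cq"] <= 0).any():
        raise ValueError("Cq values must be positive")
    means = df.groupby(["sample_id", "group", "gene"])["cq"].mean().reset_index()
    wide = means.pivot_table(index=["sample_id", "group"], columns="gene", values="cq").reset_index()
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from table")
    bad = wide[wide[reference_gene].isna() | wide[target_gene].isna()]
    if len(bad):
        warnings.warn(f"excluding {len(bad)} sample(s) missing a gene: {list(bad['sample_id'])}", stacklevel=2)
        wide = wide.dropna(subset=[target_gene, reference_gene])
    wide = wide.assign(dct=wide[target_gene] - wide[reference_gene])
    if reference_group not in set(wide["group"]):
        raise ValueError(f"reference group {reference_group!r} not present")
    group_dct = wide.groupby("group")["dct"].mean()
    ref_dct = group_dct[reference_group]
    ddct = {g: float(v - ref_dct) for g, v in group_dct.items()}
    fold = {g: float(2.0 ** (-d)) for g, d in ddct.items()}
    per_sample = wide[["sample_id", "group", "dct"]].reset_index(drop=True)
    return FoldChangeResult(
        per_sample_dct=per_sample,
        ddct=ddct,
        fold_change=fold,
        reference_group=reference_group,
    )
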