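"""Muscle-fat% and muscle volume quantification.

The biomarker is the percentage of voxels inside a 3D muscle mask whose
attenuation lies strictly below a threshold (default -20 HU).  Quantification
always runs on raw HU volumes, never on clipped or normalized ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import CTVolume, LabelMap, check_aligned
from .taxonomy import MUSCLE_GROUPS, labels_for_group

#: Columns of the metrics table produced by :func:`quantify_all`.
METRICS_COLUMNS = ["group", "side", "n_voxels", "n_fat_voxels", "fat_percent", "volume_mL"]


@dataclass(frozen=True)
class FatQuantConfig:
    """Fat-threshold configuration.

    ``comparison`` is fixed to strict "below": a voxel exactly at the
    threshold counts as muscle, not fat.
    """

    fat_threshold_hu: float = -20.0
    merge_bilateral: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.fat_threshold_hu):
            raise ValueError("fat threshold must be finite")


def muscle_fat_percent(vol: CTVolume, mask: np.ndarray,
                       cfg: FatQuantConfig | None = None) -> float:
    """Percent of mask voxels with HU strictly below the threshold.

    Raises on an empty mask (distinct from a 0% result) or shape mismatch.
    """
    cfg = cfg or FatQuantConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: fat percent undefined (not 0%)")
    n_fat = int(np.count_nonzero(vol.voxels[mask] < cfg.fat_threshold_hu))
    return 100.0 * n_fat / n


def muscle_volume(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Mask volume in mL: voxel count x product of spacings (mm^3) / 1000."""
    mask = np.asarray(mask, dtype=bool)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: volume is trivially 0 but likely an error")
    return n * float(np.prod(spacing)) / 1000.0


def fat_voxel_mask(vol: CTVolume, labels: LabelMap,
                   cfg: FatQuantConfig | None = None) -> np.ndarray:
    """Boolean mask of fat-classified voxels inside any muscle label.

    This is the voxel-filter overlay used for visual QC: low-attenuation
    voxels within the segmentation, everything else False.
    """
    cfg = cfg or FatQuantConfig()
    check_aligned(vol, labels)
    return (labels.labels > 0) & (vol.voxels < cfg.fat_threshold_hu)


def quantify_all(vol: CTVolume, labels: LabelMap,
                 cfg: FatQuantConfig | None = None) -> pd.DataFrame:
    """Per-muscle-group fat% and volume table.

    With ``merge_bilateral`` (default) the two sides are pooled before the
    fat/total division — the ratio is computed over the union mask, not
    averaged across sides.  Groups with zero labeled voxels are absent from
    the output (not reported as 0%).
    """
    cfg = cfg or FatQuantConfig()
    check_aligned(vol, labels)
    vox_vol = float(np.prod(labels.spacing))

    lab = labels.labels
    hu = vol.voxels
    counts = np.bincount(lab.ravel(), minlength=19)
    fat = (hu < cfg.fat_threshold_hu).ravel()
    fat_counts = np.bincount(lab.ravel()[fat], minlength=19)

    rows = []
    for group in MUSCLE_GROUPS:
        left, right = labels_for_group(group)
        if cfg.merge_bilateral:
            n = int(counts[left] + counts[right])
            if n == 0:
                continue
            nf = int(fat_counts[left] + fat_counts[right])
            rows.append((group, "both", n, nf, 100.0 * nf / n, n * vox_vol / 1000.0))
        else:
            for side, label in (("left", left), ("right", right)):
                n = int(counts[label])
                if n == 0:
                    continue
                nf = int(fat_counts[label])
                rows.append((group, side, n, nf, 100.0 * nf / n, n * vox_vol / 1000.0))
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def absent_groups(labels: LabelMap) -> list[str]:
    """Muscle groups with no labeled voxels on either side."""
    counts = np.bincount(labels.labels.ravel(), minlength=19)
    out = []
    for group in MUSCLE_GROUPS:
        left, right = labels_for_group(group)
        if counts[left] + counts[right] == 0:
            out.append(group)
    return out
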