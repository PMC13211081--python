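"""Segmentation agreement metrics and the compound soft-Dice + cross-entropy loss.

The loss is a reference implementation, not a training objective here:
L_total = L_Dice + L_CE, where L_Dice is the global soft Dice loss (sums
taken jointly over classes and voxels; a per-class-averaged variant is
available behind a flag) and L_CE is the mean over voxels of the voxel-wise
cross-entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_LOG_FLOOR = 1e-12


@dataclass
class ProbabilityField:
    """Predicted class probabilities ``p`` and one-hot ground truth ``g``.

    Both arrays have shape (n_voxels, n_classes); per-voxel probabilities
    must sum to 1 (within 1e-6) and g must be exactly one-hot.
    """

    p: np.ndarray
    g: np.ndarray
    epsilon: float = 1e-5

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        self.g = np.asarray(self.g, dtype=np.float64)
        if self.p.shape != self.g.shape or self.p.ndim != 2:
            raise ValueError("p and g must be 2D (voxels x classes) with equal shape")
        if np.any(self.p < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("per-voxel class probabilities must sum to 1")
        onehot = (self.g == 1.0).sum(axis=1) == 1
        if not (np.all(np.isin(self.g, (0.0, 1.0))) and np.all(onehot)):
            raise ValueError("g must be one-hot")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a & b| / (|a| + |b|) between two binary masks.

    Both masks empty returns 1.0 with a warning (absent-structure
    convention); exactly one empty returns 0.0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        warnings.warn("both masks empty; Dice defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def macro_average(per_muscle) -> float:
    """Arithmetic mean of per-muscle Dice values."""
    values = np.asarray(list(per_muscle), dtype=float)
    if values.size == 0:
        raise ValueError("cannot macro-average an empty list")
    return float(values.mean())


def dice_ce_loss(f: ProbabilityField, per_class: bool = False
                 ) -> tuple[float, float, float]:
    """(L_total, L_Dice, L_CE) for a probability field.

    ``per_class=False`` (default) computes the global soft Dice: one ratio
    with sums over classes and voxels jointly.  ``per_class=True`` averages
    the per-class soft Dice losses instead.
    """
    p, g, eps = f.p, f.g, f.epsilon
    if per_class:
        num = 2.0 * (p * g).sum(axis=0) + eps
        den = (p ** 2).sum(axis=0) + (g ** 2).sum(axis=0) + eps
        l_dice = float((1.0 - num / den).mean())
    else:
        num = 2.0 * float((p * g).sum()) + eps
        den = float((p ** 2).sum()) + float((g ** 2).sum()) + eps
        l_dice = 1.0 - num / den
    l_ce = float(-(g * np.log(np.maximum(p, _LOG_FLOOR))).sum(axis=1).mean())
    return l_dice + l_ce, l_dice, l_ce


def dice_table(per_muscle: dict[str, float]) -> pd.DataFrame:
    """Per-muscle Dice table with a trailing macro-average row."""
    rows = [{"muscle": m, "dice": v} for m, v in per_muscle.items()]
    rows.append({"muscle": "macro_average",
                 "dice": macro_average(per_muscle.values())})
    return pd.DataFrame(rows)


def dice_per_group(pred_labels: np.ndarray, true_labels: np.ndarray,
                   taxonomy: dict[int, tuple[str, str]]) -> dict[str, float]:
    """Bilateral-merged Dice per muscle group between two label maps."""
    if pred_labels.shape != true_labels.shape:
        raise ValueError("label map shapes differ")
    groups = sorted({g for g, _ in taxonomy.values()})
    out: dict[str, float] = {}
    for group in groups:
        labs = [lab for lab, (g, _) in taxonomy.items() if g == group]
        a = np.isin(pred_labels, labs)
        b = np.isin(true_labels, labs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[group] = dice(a, b)
    return out
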