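"""HU volume / label-map containers, NIfTI I/O, resampling, and model preprocessing.

Internal axis convention is fixed: axis 0 is craniocaudal (z), axes 1-2 are
in-plane (y = antero-posterior, x = left-right).  Spacing is given in mm per
axis in the same (z, y, x) order.  NIfTI affines are honored on read (files
are brought to canonical RAS orientation first) and the data reordered to
this convention.

Quantification (``trunkct.fatquant``) must always run on raw HU volumes;
:func:`preprocess_for_model` exists as a standalone reference transform for
the segmentation-model input path and returns a new volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .taxonomy import default_taxonomy


@dataclass
class CTVolume:
    """A 3D HU-valued image with voxel spacing.

    Attributes
    ----------
    voxels : ndarray, shape (nz, ny, nx), float
        Hounsfield units.
    spacing : tuple of float
        mm per axis, (z, y, x) order.
    origin : tuple of float
        World position (mm) of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.voxels.shape}")
        if min(self.voxels.shape) < 1:
            raise ValueError("every axis must have at least one voxel")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelMap:
    """Integer mask volume aligned to a :class:`CTVolume`.

    ``taxonomy`` maps each nonzero label to a ``(group, side)`` pair; label 0
    is background and never appears in the taxonomy.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    taxonomy: dict[int, tuple[str, str]] = field(default_factory=default_taxonomy)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.origin = tuple(float(o) for o in self.origin)
        present = set(np.unique(self.labels).tolist()) - {0}
        unknown = sorted(present - set(self.taxonomy))
        if unknown:
            raise ValueError(f"labels not in taxonomy: {unknown}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask_for(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class PreprocessSpec:
    """Intensity clipping / resampling parameters for the model-input path."""

    clip_low: float = -95.0
    clip_high: float = 116.0
    target_spacing: tuple[float, float, float] = (2.5, 0.871, 0.871)

    def __post_init__(self) -> None:
        if not self.clip_low < self.clip_high:
            raise ValueError("clip_low must be < clip_high")
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target spacing must be positive")


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: tuple[float, float, float],
            origin: tuple[float, float, float]) -> np.ndarray:
    # on-disk axis order is (x, y, z); ours is (z, y, x)
    aff = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    aff[:3, 3] = (origin[2], origin[1], origin[0])
    return aff


def write_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a CTVolume as NIfTI (.nii or .nii.gz)."""
    data = np.transpose(vol.voxels, (2, 1, 0)).astype(np.float32)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI volume, reorienting to the internal (z, y, x) convention."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    t = img.affine[:3, 3]
    return CTVolume(data, spacing, origin=(float(t[2]), float(t[1]), float(t[0])))


def write_labels(lab: LabelMap, path: str | Path) -> None:
    data = np.transpose(lab.labels, (2, 1, 0)).astype(np.int16)
    img = nib.Nifti1Image(data, _affine(lab.spacing, lab.origin))
    nib.save(img, str(path))


def read_labels(path: str | Path,
                taxonomy: dict[int, tuple[str, str]] | None = None) -> LabelMap:
    """Read a NIfTI label map; unknown labels raise with the offending values."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    data = np.rint(data).astype(np.int32)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    t = img.affine[:3, 3]
    return LabelMap(
        data, spacing,
        taxonomy=taxonomy if taxonomy is not None else default_taxonomy(),
        origin=(float(t[2]), float(t[1]), float(t[0])),
    )


def check_aligned(vol: CTVolume, lab: LabelMap) -> None:
    if vol.shape != lab.shape:
        raise ValueError(f"shape mismatch: volume {vol.shape} vs labels {lab.shape}")
    if not np.allclose(vol.spacing, lab.spacing, rtol=1e-6):
        raise ValueError(f"spacing mismatch: {vol.spacing} vs {lab.spacing}")


# ---------------------------------------------------------------------------
# Resampling

def _target_shape(shape: tuple[int, ...], spacing_in, spacing_out) -> tuple[int, ...]:
    # output extent covers the input's physical extent
    return tuple(
        max(1, int(np.ceil(n * s_in / s_out)))
        for n, s_in, s_out in zip(shape, spacing_in, spacing_out)
    )


def _source_coords(n_out: int, s_out: float, s_in: float, n_in: int) -> np.ndarray:
    # voxel centers at index*spacing; clamp to the input grid
    c = np.arange(n_out) * (s_out / s_in)
    return np.clip(c, 0.0, n_in - 1.0)


def resample(obj: CTVolume | LabelMap, spec: PreprocessSpec) -> CTVolume | LabelMap:
    """Resample a volume or label map onto ``spec.target_spacing``.

    Images use cubic spline interpolation in-plane and nearest-neighbour
    along z; label maps use nearest-neighbour on every axis (no new labels
    are ever introduced).
    """
    is_label = isinstance(obj, LabelMap)
    data = obj.labels if is_label else obj.voxels
    if min(data.shape) < 2:
        raise ValueError("cannot resample a degenerate (single-voxel) axis")
    sp_in, sp_out = obj.spacing, spec.target_spacing
    shape_out = _target_shape(data.shape, sp_in, sp_out)
    zc = _source_coords(shape_out[0], sp_out[0], sp_in[0], data.shape[0])
    yc = _source_coords(shape_out[1], sp_out[1], sp_in[1], data.shape[1])
    xc = _source_coords(shape_out[2], sp_out[2], sp_in[2], data.shape[2])

    z_idx = np.rint(zc).astype(int)
    if is_label:
        y_idx = np.rint(yc).astype(int)
        x_idx = np.rint(xc).astype(int)
        out = data[np.ix_(z_idx, y_idx, x_idx)]
        return LabelMap(out, sp_out, taxonomy=dict(obj.taxonomy), origin=obj.origin)

    # nearest along z first, then cubic in-plane per slice
    picked = data[z_idx]
    yy, xx = np.meshgrid(yc, xc, indexing="ij")
    coords = np.stack([yy.ravel(), xx.ravel()])
    out = np.empty((shape_out[0], shape_out[1], shape_out[2]), dtype=np.float64)
    for k in range(shape_out[0]):
        out[k] = ndimage.map_coordinates(
            picked[k], coords, order=3, mode="nearest"
        ).reshape(shape_out[1], shape_out[2])
    return CTVolume(out, sp_out, origin=obj.origin)


def preprocess_for_model(vol: CTVolume, spec: PreprocessSpec | None = None) -> CTVolume:
    """Clip HU to ``[clip_low, clip_high]`` then z-score over the whole volume.

    Raises if the clipped volume has zero variance (z-score undefined).
    Returns a new CTVolume; the input is never modified.
    """
    spec = spec if spec is not None else PreprocessSpec()
    clipped = np.clip(vol.voxels, spec.clip_low, spec.clip_high)
    sd = float(clipped.std())  # population SD (ddof=0)
    if sd == 0.0:
        raise ValueError("zero intensity variance after clipping; z-score undefined")
    z = (clipped - clipped.mean()) / sd
    return replace(vol, voxels=z)
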