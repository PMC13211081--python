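"""Synthetic CT phantom, cohort, and rater-measurement generators.

Everything downstream (fat quantification, Cobb geometry, reliability,
correlation analysis) is validated against these generators because they
carry exact ground truth:

* :func:`generate_phantom` builds an HU volume with nine bilateral muscle
  compartments (elliptic cylinders at ordered craniocaudal stations,
  mirrored across the mid-sagittal plane), each planted with an exact fat
  fraction, plus a stack of vertebral bodies along a circular arc whose
  tangent rotation between the first and last stations is the planted Cobb
  angle.  The returned endplate lines are analytic, not voxel-derived.
* :func:`generate_cohort` draws a cohort with a latent degeneration score
  shared between Cobb angle and per-muscle fat%, with confounder cases
  (surgery decouples Cobb; atrophy forces paraspinal fat% into (50, 90]).
* :func:`simulate_raters` adds per-rater bias and i.i.d. rating noise to a
  vector of true angles.

All generators take an explicit integer seed and are bit-reproducible; no
global random state is touched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cobb import EndplatePair
from .fatquant import METRICS_COLUMNS
from .imaging import CTVolume, LabelMap
from .reliability import RaterMatrix
from .taxonomy import MUSCLE_GROUPS, default_taxonomy, labels_for_group

#: Craniocaudal placement order (superior -> inferior) of the nine groups.
STATION_ORDER: tuple[str, ...] = (
    "trapezius",
    "rhomboid",
    "paraspinal",
    "latissimus_dorsi",
    "quadratus_lumborum",
    "psoas",
    "iliacus",
    "rectus_femoris",
    "vastus",
)

_DEFAULT_FAT_FRACTIONS = {
    "psoas": 0.05,
    "quadratus_lumborum": 0.14,
    "paraspinal": 0.15,
    "latissimus_dorsi": 0.16,
    "iliacus": 0.045,
    "rectus_femoris": 0.02,
    "rhomboid": 0.022,
    "trapezius": 0.02,
    "vastus": 0.025,
}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic CT phantom."""

    grid_shape: tuple[int, int, int] = (90, 96, 96)
    spacing: tuple[float, float, float] = (2.5, 0.871, 0.871)
    muscle_groups: tuple[str, ...] = MUSCLE_GROUPS
    per_group_fat_fraction: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FAT_FRACTIONS))
    hu_muscle_mean: float = 50.0
    hu_muscle_sd: float = 10.0
    hu_fat_mean: float = -90.0
    hu_fat_sd: float = 10.0
    hu_background: float = -1000.0
    hu_bone: float = 700.0
    planted_cobb: float = 38.6
    seed: int = 0

    def validate(self) -> None:
        if any(int(n) < 8 for n in self.grid_shape):
            raise ValueError("grid too small for compartment placement")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        unknown = set(self.muscle_groups) - set(MUSCLE_GROUPS)
        if unknown:
            raise ValueError(f"unknown muscle groups: {sorted(unknown)}")
        for g in self.muscle_groups:
            f = self.per_group_fat_fraction.get(g, 0.0)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fat fraction for {g} outside [0, 1]: {f}")
        # both HU tails must be well clear of the -20 threshold so that
        # threshold recovery error is purely combinatorial
        if not self.hu_fat_mean + 4 * self.hu_fat_sd < -20.0:
            raise ValueError("fat HU distribution too close to -20 threshold")
        if not self.hu_muscle_mean - 4 * self.hu_muscle_sd > -20.0:
            raise ValueError("muscle HU distribution too close to -20 threshold")
        if not 0.0 <= self.planted_cobb < 90.0:
            raise ValueError("planted Cobb must lie in [0, 90)")

    def to_json(self) -> str:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["spacing"] = list(self.spacing)
        d["muscle_groups"] = list(self.muscle_groups)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["spacing"] = tuple(d["spacing"])
        d["muscle_groups"] = tuple(d["muscle_groups"])
        return cls(**d)


@dataclass
class CohortSpec:
    """Parameters of the synthetic correlation cohort.

    ``per_muscle_loading`` is the correlation of each muscle's fat% with the
    latent degeneration score; ``cobb_loading`` plays the same role for the
    Cobb angle (1.0 makes Cobb affine in the latent).
    """

    n_cases: int = 433
    cobb_mean: float = 38.6
    cobb_sd: float = 13.5
    cobb_loading: float = 1.0
    per_muscle_fat_mean: dict[str, float] = field(
        default_factory=lambda: {g: 100.0 * f for g, f in _DEFAULT_FAT_FRACTIONS.items()})
    per_muscle_fat_sd: dict[str, float] = field(
        default_factory=lambda: {g: 5.0 for g in MUSCLE_GROUPS})
    per_muscle_loading: dict[str, float] = field(
        default_factory=lambda: {g: 0.0 for g in MUSCLE_GROUPS})
    n_surgery: int = 0
    n_atrophy: int = 0
    n_fracture: int = 0
    n_transitional: int = 0
    sex_fraction_male: float = 0.57
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for name in ("n_surgery", "n_atrophy", "n_fracture", "n_transitional"):
            v = getattr(self, name)
            if not 0 <= v <= self.n_cases:
                raise ValueError(f"{name} must lie in [0, n_cases]")
        if not -1.0 <= self.cobb_loading <= 1.0:
            raise ValueError("cobb_loading must lie in [-1, 1]")
        for g, lam in self.per_muscle_loading.items():
            if not -1.0 <= lam <= 1.0:
                raise ValueError(f"loading for {g} outside [-1, 1]")
        if self.cobb_sd < 0 or any(s < 0 for s in self.per_muscle_fat_sd.values()):
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.sex_fraction_male <= 1.0:
            raise ValueError("sex_fraction_male must lie in [0, 1]")


@dataclass
class RaterNoiseSpec:
    """k-rater measurement noise: per-rater additive bias + i.i.d. error."""

    k_raters: int = 4
    per_rating_error_sd: float = 3.69
    per_rater_bias: tuple[float, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.k_raters < 2:
            raise ValueError("need at least 2 raters")
        if self.per_rating_error_sd < 0:
            raise ValueError("error SD must be >= 0")
        if self.per_rater_bias is not None and len(self.per_rater_bias) != self.k_raters:
            raise ValueError("per_rater_bias length must equal k_raters")


@dataclass
class PhantomResult:
    volume: CTVolume
    labels: LabelMap
    ground_truth: pd.DataFrame
    endplates: EndplatePair
    arc_length_mm: float
    arc_radius_mm: float  # inf when planted Cobb is 0
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Phantom geometry

def _station_layout(spec: PhantomSpec) -> dict[str, tuple[int, int]]:
    """z-slice range [lo, hi) per group, superior to inferior."""
    nz = spec.grid_shape[0]
    n_st = len(STATION_ORDER)
    st_len = nz // n_st
    used = max(2, int(round(st_len * 0.8)))
    layout = {}
    for i, group in enumerate(STATION_ORDER):
        lo = i * st_len
        layout[group] = (lo, lo + used)
    return layout


def _compartment_mask(spec: PhantomSpec, zlo: int, zhi: int,
                      cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    nz, ny, nx = spec.grid_shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    inplane = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    mask = np.zeros(spec.grid_shape, dtype=bool)
    mask[zlo:zhi] = inplane
    return mask


def _spine_arc(spec: PhantomSpec):
    """Arc centerline parameters and analytic endplate lines, all in mm.

    The centerline starts near the grid top at the mid-sagittal (y, x)
    center and descends; its tangent rotates by planted_cobb degrees
    (symmetric +/- theta/2 tilt) over the arc length.
    """
    nz, ny, nx = spec.grid_shape
    sz, sy, sx = spec.spacing
    z_top = (nz - 1) * sz * 0.95
    length = (nz - 1) * sz * 0.85
    y_mid = (ny - 1) * sy / 2.0
    theta = math.radians(spec.planted_cobb)
    radius = math.inf if theta == 0 else length / theta

    def pos(s: float) -> tuple[float, float]:
        """(z, y) in mm at arclength s from the superior end."""
        if theta == 0:
            return z_top - s, y_mid
        phi0 = -theta / 2.0
        phi = phi0 + theta * s / length
        z = z_top - radius * (math.sin(phi) - math.sin(phi0))
        y = y_mid - radius * (math.cos(phi) - math.cos(phi0))
        return z, y

    def tangent_angle(s: float) -> float:
        if theta == 0:
            return 0.0
        return -theta / 2.0 + theta * s / length

    half_w = 15.0  # endplate half-width, mm
    lines = []
    for s in (0.0, length):
        zc, yc = pos(s)
        phi = tangent_angle(s)
        d = (math.sin(phi), math.cos(phi))  # endplate direction in (cc, ap)
        lines.append(((zc - half_w * d[0], yc - half_w * d[1]),
                      (zc + half_w * d[0], yc + half_w * d[1])))
    endplates = EndplatePair(superior_line=tuple(lines[0]),
                             inferior_line=tuple(lines[1]))
    return pos, length, radius, endplates


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build the synthetic CT volume, label map, ground truth, and endplates.

    Fat voxels are planted by exact count: round(fraction * n) voxels chosen
    uniformly at random (without replacement) over the pooled bilateral
    compartment, so the planted fraction is exact up to rounding.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.grid_shape
    sz, sy, sx = spec.spacing

    hu = np.full(spec.grid_shape, float(spec.hu_background))
    labels = np.zeros(spec.grid_shape, dtype=np.int16)

    layout = _station_layout(spec)
    x_mid = (nx - 1) / 2.0
    y_mid = (ny - 1) / 2.0
    dx = nx * 0.25        # lateral offset of compartment centers
    ax = nx * 0.16        # in-plane semi-axes, voxels
    ay = ny * 0.16

    vox_vol = sz * sy * sx
    gt_rows = []
    for group in spec.muscle_groups:
        zlo, zhi = layout[group]
        if zhi > nz:
            raise ValueError(f"compartment {group!r} exceeds the grid along z")
        left_lab, right_lab = labels_for_group(group)
        group_masks = []
        for side_lab, cx in ((left_lab, x_mid - dx), (right_lab, x_mid + dx)):
            if cx - ax < 0 or cx + ax > nx - 1 or y_mid - ay < 0 or y_mid + ay > ny - 1:
                raise ValueError(f"compartment {group!r} exceeds the grid in-plane")
            mask = _compartment_mask(spec, zlo, zhi, cx, y_mid, ax, ay)
            if np.any(labels[mask]):
                raise ValueError(f"compartment {group!r} overlaps an earlier compartment")
            labels[mask] = side_lab
            group_masks.append(mask)

        pooled = group_masks[0] | group_masks[1]
        flat = np.flatnonzero(pooled)
        n = flat.size
        frac = spec.per_group_fat_fraction.get(group, 0.0)
        n_fat = int(round(frac * n))
        fat_flat = rng.choice(flat, size=n_fat, replace=False) if n_fat else np.empty(0, int)

        vals = rng.normal(spec.hu_muscle_mean, spec.hu_muscle_sd, size=n)
        hu.ravel()[flat] = vals
        if n_fat:
            hu.ravel()[fat_flat] = rng.normal(spec.hu_fat_mean, spec.hu_fat_sd, size=n_fat)

        gt_rows.append((group, "both", n, n_fat, 100.0 * n_fat / n, n * vox_vol / 1000.0))

    # vertebral bodies along the arc
    pos, length, radius, endplates = _spine_arc(spec)
    r_v = min(6.0, dx * sx - ax * sx - 1.0)  # bone radius, mm; keep clear of muscles
    if r_v <= 0:
        raise ValueError("grid too narrow to place the spine clear of compartments")
    n_vert = 12
    h = length / n_vert
    zz = np.arange(nz)[:, None, None] * sz
    yy = np.arange(ny)[None, :, None] * sy
    xx = np.arange(nx)[None, None, :] * sx
    for i in range(n_vert):
        zc, yc = pos((i + 0.5) * h)
        ball = (zz - zc) ** 2 + (yy - yc) ** 2 + (xx - x_mid * sx) ** 2 <= r_v ** 2
        if np.any(labels[ball]):
            raise ValueError("vertebral body overlaps a muscle compartment")
        hu[ball] = spec.hu_bone

    gt = pd.DataFrame(gt_rows, columns=METRICS_COLUMNS)
    vol = CTVolume(hu, spec.spacing)
    lab = LabelMap(labels, spec.spacing, taxonomy=default_taxonomy())
    return PhantomResult(volume=vol, labels=lab, ground_truth=gt,
                         endplates=endplates, arc_length_mm=length,
                         arc_radius_mm=radius, spec=spec)


# ---------------------------------------------------------------------------
# Cohort generation

COHORT_FLAG_COLUMNS = ["surgery", "atrophy", "fracture", "transitional"]


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort with a planted latent correlation structure.

    Returns one row per case with columns: case_id, latent (hidden
    ground-truth score, retained for testing), cobb_true, cobb_mean,
    fat_<group> for each muscle, boolean flags surgery/atrophy/fracture/
    transitional, and sex ("M"/"F").

    Surgery cases have their Cobb angle replaced by an independent draw
    (decoupled from the latent); atrophy cases have paraspinal fat% drawn
    uniformly in (50, 90].  The atrophy flag is re-derived from the final
    paraspinal column, so it is consistent by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases

    z = rng.standard_normal(n)
    rho = spec.cobb_loading
    eta = rng.standard_normal(n)
    cobb = spec.cobb_mean + spec.cobb_sd * (rho * z + math.sqrt(1 - rho ** 2) * eta)

    data: dict[str, np.ndarray] = {
        "case_id": np.arange(1, n + 1),
        "latent": z,
    }
    for g in MUSCLE_GROUPS:
        lam = spec.per_muscle_loading.get(g, 0.0)
        eps = rng.standard_normal(n)
        fat = (spec.per_muscle_fat_mean.get(g, 0.0)
               + spec.per_muscle_fat_sd.get(g, 0.0)
               * (lam * z + math.sqrt(1 - lam ** 2) * eps))
        data[f"fat_{g}"] = np.maximum(fat, 0.0)

    def pick(count: int) -> np.ndarray:
        return rng.choice(n, size=count, replace=False) if count else np.empty(0, int)

    surgery_idx = pick(spec.n_surgery)
    atrophy_idx = pick(spec.n_atrophy)
    fracture_idx = pick(spec.n_fracture)
    transitional_idx = pick(spec.n_transitional)

    if surgery_idx.size:
        cobb[surgery_idx] = rng.normal(spec.cobb_mean, spec.cobb_sd,
                                       size=surgery_idx.size)
    if atrophy_idx.size:
        # uniform on (50, 90]
        data["fat_paraspinal"][atrophy_idx] = 90.0 - rng.uniform(
            0.0, 40.0, size=atrophy_idx.size)

    surgery = np.zeros(n, dtype=bool)
    surgery[surgery_idx] = True
    fracture = np.zeros(n, dtype=bool)
    fracture[fracture_idx] = True
    transitional = np.zeros(n, dtype=bool)
    transitional[transitional_idx] = True

    data["cobb_true"] = cobb
    data["cobb_mean"] = cobb.copy()
    data["surgery"] = surgery
    data["atrophy"] = data["fat_paraspinal"] > 50.0
    data["fracture"] = fracture
    data["transitional"] = transitional
    data["sex"] = np.where(rng.random(n) < spec.sex_fraction_male, "M", "F")

    cols = (["case_id", "latent", "cobb_true", "cobb_mean"]
            + [f"fat_{g}" for g in MUSCLE_GROUPS]
            + COHORT_FLAG_COLUMNS + ["sex"])
    return pd.DataFrame(data)[cols]


def simulate_raters(true_angles, noise: RaterNoiseSpec) -> RaterMatrix:
    """n x k rater matrix: entry (i, j) = true_i + bias_j + N(0, error_sd^2)."""
    noise.validate()
    true = np.asarray(true_angles, dtype=float)
    if true.ndim != 1 or true.size < 1:
        raise ValueError("true_angles must be a nonempty 1D sequence")
    if not np.all(np.isfinite(true)):
        raise ValueError("true angles must be finite")
    rng = np.random.default_rng(noise.seed)
    k = noise.k_raters
    bias = (np.zeros(k) if noise.per_rater_bias is None
            else np.asarray(noise.per_rater_bias, dtype=float))
    errors = rng.normal(0.0, noise.per_rating_error_sd, size=(true.size, k))
    values = true[:, None] + bias[None, :] + errors
    return RaterMatrix(
        values=values,
        case_ids=[f"case_{i + 1}" for i in range(true.size)],
        rater_ids=[f"rater_{j + 1}" for j in range(k)],
    )


# ---------------------------------------------------------------------------
# On-disk artifacts

def write_phantom(result: PhantomResult, out_dir: str | Path) -> dict[str, Path]:
    """Write volume + labels (NIfTI), ground-truth CSV, and spec JSON sidecar."""
    from .imaging import write_labels, write_volume  # local import avoids cycle at module load

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": out / "phantom_ct.nii.gz",
        "labels": out / "phantom_labels.nii.gz",
        "ground_truth": out / "phantom_ground_truth.csv",
        "spec": out / "phantom_spec.json",
    }
    write_volume(result.volume, paths["volume"])
    write_labels(result.labels, paths["labels"])
    result.ground_truth.to_csv(paths["ground_truth"], index=False)
    paths["spec"].write_text(result.spec.to_json())
    return paths
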