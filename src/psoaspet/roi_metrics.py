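"""Structural and metabolic ROI indices from a psoas mask.

The CT-grid mask yields volume (mL, and mL/kg of ideal body weight) and the
average attenuation coefficient (AAC, HU). For the metabolic indices the
mask is downsampled to the PET grid by exact box overlap, multiplied
against the PET SUV volume, and summarized as mean SUV, liver-normalized
SUV (N-SUV) and the N-SUV variation coefficient (VC-SUV, %) pooled over
both muscle bodies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import GeometryError, InputError, Modality, VolumeGrid
from .segmentation import SIDE_LEFT, SIDE_RIGHT, BinaryMask3D

IN_PER_CM = 1.0 / 2.54


@dataclass(frozen=True)
class RoiMetrics:
    """Per-subject psoas (or myocardial) indices."""

    volume_mL: float
    volume_per_ibw_mL_per_kg: float | None
    aac_HU: float | None
    suv_mean: float
    n_suv: float
    vc_suv_pct: float
    n_voxels_ct: int
    n_voxels_pet: int
    liver_suv_mean: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# Mask resampling CT -> PET
# ---------------------------------------------------------------------------

def _axis_overlap_matrix(src: VolumeGrid, dst: VolumeGrid, axis: int) -> np.ndarray:
    """Pairwise overlap length (mm) between voxel intervals of two grids."""
    sc = src.voxel_centers(axis)
    dc = dst.voxel_centers(axis)
    sh = src.spacing_mm[axis] / 2.0
    dh = dst.spacing_mm[axis] / 2.0
    lo = np.maximum(sc[:, None] - sh, dc[None, :] - dh)
    hi = np.minimum(sc[:, None] + sh, dc[None, :] + dh)
    return np.clip(hi - lo, 0.0, None)


def coverage_fractions(mask: np.ndarray, ct: VolumeGrid, pet: VolumeGrid) -> np.ndarray:
    """Exact fraction of each PET voxel's box covered by True CT voxels.

    CT voxels are axis-aligned boxes; the covered volume of a PET voxel is
    a separable triple sum over per-axis interval overlaps, so it is exact
    (up to float rounding), not a nearest-neighbour approximation.
    """
    wz = _axis_overlap_matrix(ct, pet, 0)
    wy = _axis_overlap_matrix(ct, pet, 1)
    wx = _axis_overlap_matrix(ct, pet, 2)
    if not (wz.any() and wy.any() and wx.any()):
        raise GeometryError("CT and PET grids do not overlap")
    m = mask.astype(np.float64)
    t = np.tensordot(m, wz, axes=(0, 0))     # (Y, X, Zp)
    t = np.tensordot(t, wy, axes=(0, 0))     # (X, Zp, Yp)
    t = np.tensordot(t, wx, axes=(0, 0))     # (Zp, Yp, Xp)
    return t / pet.voxel_volume_mm3


def downsample_mask_to_pet(
    mask: BinaryMask3D,
    ct: VolumeGrid,
    pet: VolumeGrid,
    frac_threshold: float = 0.5,
) -> BinaryMask3D:
    """Downsample a CT-grid label mask to the PET grid by box overlap.

    A PET voxel is included when the total volume fraction of its box
    covered by (either-side) mask voxels reaches ``frac_threshold``; it
    takes the side label with the majority of the coverage (ties go to the
    left label, which is checked first).
    """
    if not 0 < frac_threshold <= 1:
        raise InputError(f"frac_threshold must be in (0, 1], got {frac_threshold}")
    if mask.labels.shape != ct.shape:
        raise GeometryError("mask is not on the CT grid")
    f_left = coverage_fractions(mask.side(SIDE_LEFT), ct, pet)
    f_right = coverage_fractions(mask.side(SIDE_RIGHT), ct, pet)
    total = f_left + f_right
    include = total >= frac_threshold - 1e-12
    labels = np.where(include, np.where(f_left >= f_right, SIDE_LEFT, SIDE_RIGHT), 0)
    return BinaryMask3D(labels=labels.astype(np.uint8), grid_id="pet")


# ---------------------------------------------------------------------------
# Structural indices (CT grid)
# ---------------------------------------------------------------------------

def masked_volume(mask: BinaryMask3D, grid: VolumeGrid) -> float:
    """Volume in mL of the nonzero mask voxels on ``grid``."""
    if mask.labels.shape != grid.shape:
        raise GeometryError("mask and grid shapes differ")
    return mask.count() * grid.voxel_volume_mm3 / 1000.0


def average_attenuation(ct: VolumeGrid, mask: BinaryMask3D) -> float:
    """Mean HU over all mask voxels, both sides pooled."""
    if ct.modality is not Modality.CT_HU:
        raise InputError("average_attenuation needs a CT_HU volume")
    sel = mask.any
    if not sel.any():
        raise InputError("empty mask")
    return float(ct.data[sel].mean())


def ideal_body_weight(sex: str, height_cm: float) -> float:
    """Robinson ideal body weight (kg).

    52 kg (male) or 49 kg (female) at 60 inches, plus 1.9 / 1.7 kg per inch
    of height above 60 in; heights at or below 60 in return the base value.
    """
    if height_cm <= 0:
        raise InputError(f"height_cm must be > 0, got {height_cm}")
    height_in = height_cm * IN_PER_CM
    over = max(height_in - 60.0, 0.0)
    if sex == "male":
        return 52.0 + 1.9 * over
    if sex == "female":
        return 49.0 + 1.7 * over
    raise InputError(f"unknown sex code {sex!r}")


def normalize_volume(volume_mL: float, ibw_kg: float) -> float:
    """Muscle volume per kg of ideal body weight (mL/kg)."""
    if ibw_kg <= 0:
        raise InputError(f"ibw_kg must be > 0, got {ibw_kg}")
    return volume_mL / ibw_kg


# ---------------------------------------------------------------------------
# Metabolic indices (PET grid)
# ---------------------------------------------------------------------------

def _mask_suvs(pet_suv: VolumeGrid, mask: BinaryMask3D) -> np.ndarray:
    if pet_suv.modality is not Modality.PET_SUV:
        raise InputError("expected a PET_SUV volume (run compute_suv first)")
    if mask.labels.shape != pet_suv.shape:
        raise GeometryError("mask is not on the PET grid")
    return pet_suv.data[mask.any]


def normalized_suv(
    pet_suv: VolumeGrid, mask: BinaryMask3D, liver_suv_mean: float
) -> tuple[float, float]:
    """Mean SUV over the mask and its liver-normalized value (N-SUV)."""
    if liver_suv_mean <= 0:
        raise InputError(f"liver_suv_mean must be > 0, got {liver_suv_mean}")
    vals = _mask_suvs(pet_suv, mask)
    if vals.size == 0:
        raise InputError("empty PET-grid mask")
    suv_mean = float(vals.mean())
    return suv_mean, suv_mean / liver_suv_mean


def vc_suv(pet_suv: VolumeGrid, mask: BinaryMask3D, liver_suv_mean: float) -> float:
    """Variation coefficient of N-SUV over the mask voxels, in percent.

    100 x sample SD / mean of the per-voxel N-SUVs, left and right bodies
    pooled. The liver normalization cancels in the ratio, so the value is
    identical computed on raw SUVs; it is kept in the signature for
    interface symmetry and validation.
    """
    if liver_suv_mean <= 0:
        raise InputError(f"liver_suv_mean must be > 0, got {liver_suv_mean}")
    vals = _mask_suvs(pet_suv, mask) / liver_suv_mean
    if vals.size < 2:
        raise InputError(f"need >= 2 mask voxels, got {vals.size}")
    mean = vals.mean()
    if mean <= 0:
        raise InputError("VC-SUV undefined: mean N-SUV <= 0")
    return float(100.0 * vals.std(ddof=1) / mean)


def liver_reference(
    pet_suv: VolumeGrid,
    liver_mask: BinaryMask3D | None = None,
    sphere: tuple[tuple[float, float, float], float] | None = None,
) -> float:
    """Mean SUV of the liver reference region.

    The region is either an explicit mask on the PET grid or a sphere given
    as ``((z, y, x) centre in mm, diameter in mm)`` rasterized by voxel
    centre.
    """
    if (liver_mask is None) == (sphere is None):
        raise InputError("provide exactly one of liver_mask or sphere")
    if liver_mask is None:
        center, diameter = sphere
        sel = sphere_mask(pet_suv, center, diameter)
    else:
        if liver_mask.labels.shape != pet_suv.shape:
            raise GeometryError("liver mask is not on the PET grid")
        sel = liver_mask.any
    if not sel.any():
        raise InputError("liver reference region is empty / outside the volume")
    return float(pet_suv.data[sel].mean())


def sphere_mask(
    grid: VolumeGrid, center_mm: tuple[float, float, float], diameter_mm: float
) -> np.ndarray:
    """Boolean mask of voxels whose centre lies within a physical sphere."""
    r = diameter_mm / 2.0
    z = grid.voxel_centers(0) - center_mm[0]
    y = grid.voxel_centers(1) - center_mm[1]
    x = grid.voxel_centers(2) - center_mm[2]
    d2 = z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    return d2 <= r * r


def myocardial_metrics(
    pet_suv: VolumeGrid,
    lv_mask: BinaryMask3D,
    liver_suv_mean: float,
    min_volume_mL: float = 10.0,
) -> RoiMetrics:
    """N-SUV metrics over a left-ventricular VOI of at least ``min_volume_mL``."""
    vol = masked_volume(lv_mask, pet_suv)
    if vol < min_volume_mL:
        raise InputError(
            f"myocardial VOI of {vol:.1f} mL below the {min_volume_mL:.0f} mL minimum"
        )
    suv_mean, n_suv = normalized_suv(pet_suv, lv_mask, liver_suv_mean)
    return RoiMetrics(
        volume_mL=vol,
        volume_per_ibw_mL_per_kg=None,
        aac_HU=None,
        suv_mean=suv_mean,
        n_suv=n_suv,
        vc_suv_pct=vc_suv(pet_suv, lv_mask, liver_suv_mean),
        n_voxels_ct=0,
        n_voxels_pet=lv_mask.count(),
        liver_suv_mean=liver_suv_mean,
    )


# ---------------------------------------------------------------------------
# Full per-subject extraction
# ---------------------------------------------------------------------------

def psoas_metrics(
    ct: VolumeGrid,
    pet_suv: VolumeGrid,
    ct_mask: BinaryMask3D,
    liver_suv_mean: float,
    sex: str | None = None,
    height_cm: float | None = None,
    frac_threshold: float = 0.5,
) -> RoiMetrics:
    """Compute the full per-subject index set from a CT-grid psoas mask.

    Volume and AAC come from the CT-grid mask; SUV indices from the PET
    values under the box-overlap-downsampled mask, taken voxel-as-is with
    no interpolation.
    """
    pet_mask = downsample_mask_to_pet(ct_mask, ct, pet_suv, frac_threshold)
    vol = masked_volume(ct_mask, ct)
    suv_mean, n_suv = normalized_suv(pet_suv, pet_mask, liver_suv_mean)
    vol_norm = None
    if sex is not None and height_cm is not None:
        vol_norm = normalize_volume(vol, ideal_body_weight(sex, height_cm))
    return RoiMetrics(
        volume_mL=vol,
        volume_per_ibw_mL_per_kg=vol_norm,
        aac_HU=average_attenuation(ct, ct_mask),
        suv_mean=suv_mean,
        n_suv=n_suv,
        vc_suv_pct=vc_suv(pet_suv, pet_mask, liver_suv_mean),
        n_voxels_ct=ct_mask.count(),
        n_voxels_pet=pet_mask.count(),
        liver_suv_mean=liver_suv_mean,
    )
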