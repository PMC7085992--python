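"""Volume I/O, SUV conversion, and CT/PET geometry checks.

Volumes are held in a single canonical layout: a 3D array indexed
``(slice, row, col)`` with slices stacked along the cranio-caudal axis,
0-based indices and half-open slice ranges throughout. NIfTI is the
interchange format; DICOM series are supported read-only.
"""

from __future__ import annotations

import enum
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)


class Modality(enum.Enum):
    """What the voxel values of a :class:`VolumeGrid` mean."""

    CT_HU = "CT_HU"               # Hounsfield units
    PET_KBQ_ML = "PET_KBQ_ML"     # activity concentration, kBq/mL
    PET_SUV = "PET_SUV"           # standardized uptake value, dimensionless


class GeometryError(ValueError):
    """Inconsistent or non-overlapping volume geometry."""


class InputError(ValueError):
    """Invalid metadata or file contents."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar image with voxel spacing and physical origin.

    Parameters
    ----------
    data
        Array of shape ``(n_slices, n_rows, n_cols)``.
    spacing_mm
        Voxel size ``(dz, dy, dx)`` in millimetres; all components positive.
    origin_mm
        Physical position ``(z, y, x)`` of the centre of voxel (0, 0, 0).
    modality
        One of :class:`Modality`; PET concentration volumes are clamped to
        non-negative values on construction (negative voxels are
        reconstruction artifacts).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.CT_HU

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise InputError(f"expected a 3D array, got ndim={data.ndim}")
        if any(s <= 0 for s in self.spacing_mm):
            raise GeometryError(f"non-positive spacing {self.spacing_mm}")
        if self.modality is Modality.CT_HU:
            if not np.all(np.isfinite(data)):
                raise InputError("CT volume contains non-finite values")
        else:
            n_neg = int(np.sum(data < 0))
            if n_neg:
                log.info("clamped %d negative PET voxels to 0", n_neg)
                data = np.clip(data, 0.0, None)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing_mm
        return dz * dy * dx

    def extent_mm(self) -> np.ndarray:
        """Physical bounding box [(lo_z, hi_z), (lo_y, hi_y), (lo_x, hi_x)].

        Voxels are boxes centred on their grid positions, so the extent
        reaches half a voxel beyond the first/last centres.
        """
        lo = np.asarray(self.origin_mm) - np.asarray(self.spacing_mm) / 2.0
        hi = lo + np.asarray(self.shape) * np.asarray(self.spacing_mm)
        return np.stack([lo, hi], axis=1)

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis (0=z,1=y,2=x)."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(n)


@dataclass(frozen=True)
class ScanMeta:
    """Per-scan metadata required for SUV computation and IBW normalization."""

    body_weight_kg: float
    injected_dose_MBq: float
    sex: str = "male"
    height_cm: float = 170.0
    liver_suv_mean: float | None = None

    def __post_init__(self):
        if self.body_weight_kg <= 0:
            raise InputError(f"body_weight_kg must be > 0, got {self.body_weight_kg}")
        if self.injected_dose_MBq <= 0:
            raise InputError(f"injected_dose_MBq must be > 0, got {self.injected_dose_MBq}")
        if self.height_cm <= 0:
            raise InputError(f"height_cm must be > 0, got {self.height_cm}")
        if self.sex not in ("male", "female"):
            raise InputError(f"sex must be 'male' or 'female', got {self.sex!r}")


# ---------------------------------------------------------------------------
# NIfTI / DICOM I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike, modality_hint: Modality = Modality.CT_HU) -> VolumeGrid:
    """Read a NIfTI file or a DICOM series directory into a VolumeGrid.

    NIfTI volumes are reoriented to closest-canonical (RAS) and transposed so
    the array is (slice, row, col). DICOM CT stored values are rescaled to HU
    with the per-slice rescale slope/intercept.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        return _read_dicom_series(path, modality_hint)
    return _read_nifti(path, modality_hint)


def _read_nifti(path: str, modality: Modality) -> VolumeGrid:
    import nibabel as nib

    img = nib.as_closest_canonical(nib.load(path))
    data_xyz = np.asarray(img.dataobj, dtype=np.float64)
    if data_xyz.ndim != 3:
        raise InputError(f"{path}: expected 3D NIfTI, got shape {data_xyz.shape}")
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
    origin_xyz = img.affine[:3, 3]
    return VolumeGrid(
        data=np.transpose(data_xyz, (2, 1, 0)),
        spacing_mm=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        origin_mm=(float(origin_xyz[2]), float(origin_xyz[1]), float(origin_xyz[0])),
        modality=modality,
    )


def write_volume(vol: VolumeGrid, path: str | os.PathLike) -> None:
    """Write a VolumeGrid as NIfTI-1, inverse of :func:`read_volume`."""
    import nibabel as nib

    dz, dy, dx = vol.spacing_mm
    oz, oy, ox = vol.origin_mm
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = (ox, oy, oz)
    img = nib.Nifti1Image(np.transpose(vol.data, (2, 1, 0)), affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, os.fspath(path))


def _read_dicom_series(path: str, modality: Modality) -> VolumeGrid:
    import pydicom

    files = sorted(
        os.path.join(path, f) for f in os.listdir(path) if not f.startswith(".")
    )
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except Exception:  # non-DICOM clutter in the directory
            continue
    if not datasets:
        raise InputError(f"{path}: no readable DICOM files")

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise InputError(f"{path}: mixed series UIDs {sorted(uids)}")

    # sort slices along the slice normal
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    z_pos = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(z_pos) > 1:
        dz_all = np.diff(z_pos)
        dz = float(np.mean(dz_all))
        if dz <= 0 or np.max(np.abs(dz_all - dz)) > 0.01 * abs(dz) + 1e-3:
            raise GeometryError(f"{path}: inconsistent slice spacing {dz_all}")
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    data = np.stack(slices, axis=0)

    ds0 = datasets[0]
    dy, dx = (float(v) for v in ds0.PixelSpacing)
    ipp = [float(v) for v in ds0.ImagePositionPatient]
    return VolumeGrid(
        data=data,
        spacing_mm=(dz, dy, dx),
        origin_mm=(ipp[2], ipp[1], ipp[0]),
        modality=modality,
    )


# ---------------------------------------------------------------------------
# SUV conversion
# ---------------------------------------------------------------------------

def compute_suv(pet: VolumeGrid, meta: ScanMeta) -> VolumeGrid:
    """Convert an activity-concentration PET volume to SUV.

    SUV = concentration (kBq/mL) x body weight (kg) / injected dose (MBq).
    The units cancel because 1 MBq = 1000 kBq and 1 kg of tissue occupies
    roughly 1000 mL, so SUV is reported dimensionless. Concentrations are
    assumed already decay-corrected by the scanner.
    """
    if pet.modality is not Modality.PET_KBQ_ML:
        raise InputError(f"expected PET_KBQ_ML volume, got {pet.modality}")
    factor = meta.body_weight_kg / meta.injected_dose_MBq
    return replace(pet, data=pet.data * factor, modality=Modality.PET_SUV)


def suv_to_concentration(pet_suv: VolumeGrid, meta: ScanMeta) -> VolumeGrid:
    """Inverse of :func:`compute_suv` (used by the phantom generator)."""
    if pet_suv.modality is not Modality.PET_SUV:
        raise InputError(f"expected PET_SUV volume, got {pet_suv.modality}")
    factor = meta.injected_dose_MBq / meta.body_weight_kg
    return replace(pet_suv, data=pet_suv.data * factor, modality=Modality.PET_KBQ_ML)


# ---------------------------------------------------------------------------
# Registration check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentReport:
    """Result of a CT/PET co-registration geometry check."""

    origin_offset_mm: tuple[float, float, float]
    extent_overlap_fraction: float
    aligned: bool
    notes: tuple[str, ...] = field(default_factory=tuple)


def check_registration(ct: VolumeGrid, pet: VolumeGrid, tol_mm: float = 2.0) -> AlignmentReport:
    """Verify that two volumes cover the same physical space.

    The offset reported is between the physical *centres* of the two
    bounding boxes (grids of different resolution legitimately have
    different voxel-(0,0,0) origins). Misalignment beyond ``tol_mm`` on any
    axis fails the check; disjoint extents raise :class:`GeometryError`.
    """
    ext_ct = ct.extent_mm()
    ext_pet = pet.extent_mm()
    lo = np.maximum(ext_ct[:, 0], ext_pet[:, 0])
    hi = np.minimum(ext_ct[:, 1], ext_pet[:, 1])
    if np.any(hi <= lo):
        raise GeometryError("CT and PET physical extents are disjoint")

    inter = float(np.prod(hi - lo))
    vol_ct = float(np.prod(ext_ct[:, 1] - ext_ct[:, 0]))
    overlap = inter / vol_ct
    center_ct = ext_ct.mean(axis=1)
    center_pet = ext_pet.mean(axis=1)
    offset = center_pet - center_ct
    aligned = bool(np.all(np.abs(offset) <= tol_mm))

    notes = []
    if ct.spacing_mm != pet.spacing_mm:
        notes.append(
            f"resolutions differ: {ct.spacing_mm} mm vs {pet.spacing_mm} mm"
        )
    return AlignmentReport(
        origin_offset_mm=tuple(float(v) for v in offset),
        extent_overlap_fraction=overlap,
        aligned=aligned,
        notes=tuple(notes),
    )
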