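"""Digital PET/CT phantoms and simulated cohorts with known ground truth.

The imaging phantom emulates the abdominal anatomy the pipeline operates
on: two paraspinal elliptic-cylinder muscle bodies with a per-slice radius
taper, a high-attenuation vertebral block between them, and a liver
ellipsoid as the SUV reference region — on a fine CT grid and a coarser,
deliberately offset PET grid. CT voxels carry tissue HU plus Gaussian
noise; PET voxels carry tissue SUV plus an i.i.d. Gaussian uptake texture
inside the muscles (which sets the generative VC-SUV) and are stored as
activity concentration so the SUV conversion round-trips through the scan
metadata.

The cohort simulator draws the seven prognostic covariates from
configurable means/SDs and generates exponential proportional-hazards
survival times with independent uniform censoring, so stratification and
Cox-regression behaviour can be tested against known effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .imaging_io import Modality, ScanMeta, VolumeGrid, suv_to_concentration
from .segmentation import SIDE_LEFT, SIDE_RIGHT, BinaryMask3D
from .survival import SEVEN_VARIABLES


class PhantomSpecError(ValueError):
    """Phantom geometry violates its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic PET/CT pair.

    Grid defaults give a 256 x 256 x 40 CT at 1 x 1 x 3 mm and a
    64 x 64 x 40 PET at 4 x 4 x 3 mm covering the same physical extent,
    with the PET grid shifted in-plane by ``pet_origin_shift_mm`` to
    exercise the box-overlap downsampler. All positions are physical mm in
    (z, y, x) order.
    """

    # grids
    ct_shape: tuple[int, int, int] = (40, 256, 256)
    ct_spacing_mm: tuple[float, float, float] = (3.0, 1.0, 1.0)
    pet_shape: tuple[int, int, int] = (40, 64, 64)
    pet_spacing_mm: tuple[float, float, float] = (3.0, 4.0, 4.0)
    pet_origin_shift_mm: tuple[float, float, float] = (0.0, 1.5, 1.5)

    # muscle geometry: two elliptic cylinders flanking the vertebral block
    muscle_center_offset_mm: tuple[float, float] = (10.0, 45.0)  # (y, |x|) from centre
    muscle_semi_axes_mm: tuple[float, float] = (28.0, 20.0)      # (ay, ax) at mid-stack
    muscle_slice_range: tuple[int, int] = (4, 36)                # half-open
    taper_end_scale: float = 0.80                                # radii scale at range ends

    # vertebral block (square prism through all slices)
    vertebra_half_width_mm: float = 16.0
    vertebra_hu: float = 700.0
    vertebra_suv: float = 0.5

    # liver ellipsoid
    liver_center_mm: tuple[float, float, float] = (24.0, 67.5, 57.5)
    liver_semi_axes_mm: tuple[float, float, float] = (15.0, 25.0, 30.0)
    liver_hu: float = 60.0
    liver_suv_mean: float = 2.0

    # tissue values (disease-cohort magnitudes: AAC ~39.4 HU,
    # liver-normalized uptake 0.45 with 8% voxel-wise CV)
    muscle_hu_mean: float = 39.4
    background_hu: float = -80.0
    muscle_suv_mean: float = 0.90      # liver-normalized 0.45
    muscle_suv_sd: float = 0.072       # generative VC-SUV 8%
    background_suv: float = 0.40

    # acquisition noise (Gaussian, image domain)
    ct_noise_sd_hu: float = 5.0
    pet_noise_sd_suv: float = 0.02

    # scan metadata
    body_weight_kg: float = 69.0
    injected_dose_MBq: float = 345.0
    sex: str = "male"
    height_cm: float = 175.0

    seed: int = 0

    @property
    def generative_vc_pct(self) -> float:
        """CV of the muscle uptake texture implied by mean and SD, in %."""
        return 100.0 * self.muscle_suv_sd / self.muscle_suv_mean

    @property
    def generative_n_suv(self) -> float:
        return self.muscle_suv_mean / self.liver_suv_mean


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth masks and echoed generative parameters."""

    ct_mask: BinaryMask3D
    pet_mask: BinaryMask3D
    liver_ct_mask: np.ndarray
    liver_pet_mask: np.ndarray
    analytic_volume_mL: dict
    spec: PhantomSpec


def _grids(spec: PhantomSpec) -> tuple[VolumeGrid, VolumeGrid]:
    """Empty CT/PET grids with co-registered physical extents."""
    ct_origin = (0.0, 0.0, 0.0)
    ct_lo = np.asarray(ct_origin) - np.asarray(spec.ct_spacing_mm) / 2.0
    pet_origin = ct_lo + np.asarray(spec.pet_spacing_mm) / 2.0 + np.asarray(
        spec.pet_origin_shift_mm
    )
    ct = VolumeGrid(np.zeros(spec.ct_shape), spec.ct_spacing_mm, ct_origin, Modality.CT_HU)
    pet = VolumeGrid(
        np.zeros(spec.pet_shape), spec.pet_spacing_mm, tuple(pet_origin), Modality.PET_SUV
    )
    return ct, pet


def _inplane_center(spec: PhantomSpec) -> tuple[float, float]:
    cy = (spec.ct_shape[1] - 1) / 2.0 * spec.ct_spacing_mm[1]
    cx = (spec.ct_shape[2] - 1) / 2.0 * spec.ct_spacing_mm[2]
    return cy, cx


def _muscle_scale(spec: PhantomSpec, z_mm: np.ndarray) -> np.ndarray:
    """Per-slice radius scale: taper_end_scale at the range ends, 1 mid-range."""
    z0 = spec.muscle_slice_range[0] * spec.ct_spacing_mm[0]
    z1 = (spec.muscle_slice_range[1] - 1) * spec.ct_spacing_mm[0]
    zmid = (z0 + z1) / 2.0
    half = max((z1 - z0) / 2.0, 1e-9)
    frac = np.clip(np.abs(z_mm - zmid) / half, 0.0, 1.0)
    return 1.0 - (1.0 - spec.taper_end_scale) * frac


def _label_map(spec: PhantomSpec, grid: VolumeGrid) -> tuple[np.ndarray, np.ndarray]:
    """(muscle label array {0,1,2}, tissue code array) at grid voxel centres.

    Tissue codes: 0 background, 1 muscle, 2 vertebra, 3 liver.
    """
    z = grid.voxel_centers(0)[:, None, None]
    y = grid.voxel_centers(1)[None, :, None]
    x = grid.voxel_centers(2)[None, None, :]
    cy, cx = _inplane_center(spec)

    dy_off, dx_off = spec.muscle_center_offset_mm
    ay0, ax0 = spec.muscle_semi_axes_mm
    scale = _muscle_scale(spec, z)
    z0 = spec.muscle_slice_range[0] * spec.ct_spacing_mm[0] - spec.ct_spacing_mm[0] / 2.0
    z1 = (spec.muscle_slice_range[1] - 1) * spec.ct_spacing_mm[0] + spec.ct_spacing_mm[0] / 2.0
    # assign by CT slice-range in physical z so both grids see the same extent
    in_z = (z >= z0) & (z <= z1)

    labels = np.zeros(grid.shape, dtype=np.uint8)
    for side, sign in ((SIDE_LEFT, -1.0), (SIDE_RIGHT, +1.0)):
        mx = cx + sign * dx_off
        my = cy + dy_off
        inside = ((y - my) / (ay0 * scale)) ** 2 + ((x - mx) / (ax0 * scale)) ** 2 <= 1.0
        labels[np.broadcast_to(inside & in_z, grid.shape)] = side

    vert = (np.abs(y - cy) <= spec.vertebra_half_width_mm) & (
        np.abs(x - cx) <= spec.vertebra_half_width_mm
    )
    vert = np.broadcast_to(vert, grid.shape)

    lz, ly, lx = spec.liver_center_mm
    az, ay, ax = spec.liver_semi_axes_mm
    liver = ((z - lz) / az) ** 2 + ((y - ly) / ay) ** 2 + ((x - lx) / ax) ** 2 <= 1.0

    tissue = np.zeros(grid.shape, dtype=np.uint8)
    tissue[liver] = 3
    tissue[vert & (tissue == 0)] = 2
    tissue[labels > 0] = 1

    if (vert & (labels > 0)).any():
        raise PhantomSpecError("muscles intersect the vertebral block")
    if (liver & (labels > 0)).any():
        raise PhantomSpecError("liver intersects the muscles")
    return labels, tissue


def analytic_muscle_volume_mL(spec: PhantomSpec) -> float:
    """Closed-form volume of one tapered elliptic cylinder, in mL.

    Integrates pi * a(z) * b(z) over the slice range, with the linear
    radius taper applied to both semi-axes, treating each slice as a
    constant-radius slab of thickness dz evaluated at the slice centre
    (which is exactly how the voxelized truth is generated).
    """
    dz = spec.ct_spacing_mm[0]
    s0, s1 = spec.muscle_slice_range
    z_mm = (np.arange(s0, s1) * dz).astype(float)
    scale = _muscle_scale(spec, z_mm)
    ay, ax = spec.muscle_semi_axes_mm
    areas = np.pi * (ay * scale) * (ax * scale)
    return float(np.sum(areas) * dz / 1000.0)


def generate_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[VolumeGrid, VolumeGrid, PhantomTruth, ScanMeta]:
    """Generate a co-registered CT/PET pair with ground truth.

    Returns the CT volume (HU), the PET volume as activity concentration
    (kBq/mL, so ``compute_suv`` reproduces the generative SUV map), the
    truth bundle, and the scan metadata.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    ct_grid, pet_grid = _grids(spec)
    meta = ScanMeta(
        body_weight_kg=spec.body_weight_kg,
        injected_dose_MBq=spec.injected_dose_MBq,
        sex=spec.sex,
        height_cm=spec.height_cm,
        liver_suv_mean=spec.liver_suv_mean,
    )

    ct_labels, ct_tissue = _label_map(spec, ct_grid)
    pet_labels, pet_tissue = _label_map(spec, pet_grid)

    hu_by_tissue = np.array(
        [spec.background_hu, spec.muscle_hu_mean, spec.vertebra_hu, spec.liver_hu]
    )
    ct_data = hu_by_tissue[ct_tissue]
    if spec.ct_noise_sd_hu > 0:
        ct_data = ct_data + rng.normal(0.0, spec.ct_noise_sd_hu, ct_data.shape)

    suv_by_tissue = np.array(
        [spec.background_suv, spec.muscle_suv_mean, spec.vertebra_suv, spec.liver_suv_mean]
    )
    suv = suv_by_tissue[pet_tissue].astype(float)
    in_muscle = pet_tissue == 1
    if spec.muscle_suv_sd > 0:
        suv[in_muscle] += rng.normal(0.0, spec.muscle_suv_sd, int(in_muscle.sum()))
    if spec.pet_noise_sd_suv > 0:
        suv = suv + rng.normal(0.0, spec.pet_noise_sd_suv, suv.shape)
    suv = np.clip(suv, 0.0, None)

    ct = VolumeGrid(ct_data, ct_grid.spacing_mm, ct_grid.origin_mm, Modality.CT_HU)
    pet_suv = VolumeGrid(suv, pet_grid.spacing_mm, pet_grid.origin_mm, Modality.PET_SUV)
    pet = suv_to_concentration(pet_suv, meta)

    vol = analytic_muscle_volume_mL(spec)
    truth = PhantomTruth(
        ct_mask=BinaryMask3D(ct_labels, grid_id="ct"),
        pet_mask=BinaryMask3D(pet_labels, grid_id="pet"),
        liver_ct_mask=ct_tissue == 3,
        liver_pet_mask=pet_tissue == 3,
        analytic_volume_mL={"left": vol, "right": vol, "total": 2 * vol},
        spec=spec,
    )
    return ct, pet, truth, meta


def default_segmentation_seeds(spec: PhantomSpec) -> tuple[tuple[float, float], tuple[float, float]]:
    """First-slice (row, col) seed points at the two muscle centres."""
    cy, cx = _inplane_center(spec)
    dy_off, dx_off = spec.muscle_center_offset_mm
    row = (cy + dy_off) / spec.ct_spacing_mm[1]
    col_l = (cx - dx_off) / spec.ct_spacing_mm[2]
    col_r = (cx + dx_off) / spec.ct_spacing_mm[2]
    return ((row, col_l), (row, col_r))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: Covariate means/SDs emulating a spinal-onset ALS cohort at imaging.
DEFAULT_COVARIATE_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "age_years": (62.0, 12.0),
    "alsfrs_r": (39.0, 5.0),
    "spinal_cord_n_suv": (0.96, 0.30),
    "psoas_volume_mL_per_kg": (3.6, 1.02),
    "psoas_n_suv": (0.45, 0.19),
    "psoas_vc_suv_pct": (8.0, 4.0),
    "ba4_suv": (5.59, 1.30),
}

_COVARIATE_FLOORS = {
    "age_years": 18.0,
    "alsfrs_r": 0.0,
    "spinal_cord_n_suv": 0.05,
    "psoas_volume_mL_per_kg": 0.5,
    "psoas_n_suv": 0.05,
    "psoas_vc_suv_pct": 0.5,
    "ba4_suv": 0.5,
}


def generate_cohort(
    n_subjects: int = 56,
    effects: dict[str, float] | None = None,
    censoring_max_months: float = 60.0,
    baseline_rate_per_month: float = 0.017,
    seed: int | np.random.Generator = 0,
    distributions: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Simulate a cohort table with known prognostic structure.

    Covariates are independent Gaussians (floored at physiological minima,
    ALSFRS-R capped at 48). Survival times are exponential with hazard
    ``baseline_rate * exp(sum_v beta_v * z_v)`` where ``z_v`` is the
    standardized covariate and ``beta_v`` the per-SD log hazard ratio from
    ``effects`` (absent variables have no effect). Censoring times are
    independent Uniform(0, censoring_max_months); with the default baseline
    rate and no effects about 37% of subjects die before censoring.
    """
    if n_subjects < 2:
        raise ValueError(f"n_subjects must be >= 2, got {n_subjects}")
    if censoring_max_months < 0 or baseline_rate_per_month <= 0:
        raise ValueError("invalid censoring or baseline rate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    effects = effects or {}
    unknown = set(effects) - set(SEVEN_VARIABLES)
    if unknown:
        raise ValueError(f"effects on unknown variables {sorted(unknown)}")
    dists = distributions or DEFAULT_COVARIATE_DISTRIBUTIONS

    cols = {"subject_id": [f"S{i:04d}" for i in range(n_subjects)]}
    eta = np.zeros(n_subjects)
    for var in SEVEN_VARIABLES:
        mean, sd = dists[var]
        vals = rng.normal(mean, sd, n_subjects)
        vals = np.maximum(vals, _COVARIATE_FLOORS[var])
        if var == "alsfrs_r":
            vals = np.clip(vals, 0.0, 48.0)
        cols[var] = vals
        beta = effects.get(var, 0.0)
        if beta:
            eta += beta * (vals - mean) / sd

    t_event = rng.exponential(1.0 / (baseline_rate_per_month * np.exp(eta)))
    if censoring_max_months > 0:
        t_cens = rng.uniform(0.0, censoring_max_months, n_subjects)
    else:
        t_cens = np.full(n_subjects, np.inf)
    event = (t_event <= t_cens).astype(int)
    cols["followup_months"] = np.minimum(t_event, t_cens)
    cols["event"] = event
    return pd.DataFrame(cols)


def simulate_two_group(
    n_per_arm: int,
    hazard_ratio: float,
    baseline_rate_per_month: float = 0.017,
    censoring_max_months: float = 60.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Two-arm exponential survival data with a known hazard ratio.

    Returns columns ``group`` (0 reference / 1 at ``hazard_ratio``),
    ``followup_months`` and ``event``; censoring is Uniform(0, max).
    """
    if n_per_arm < 1 or hazard_ratio <= 0:
        raise ValueError("need n_per_arm >= 1 and hazard_ratio > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = 2 * n_per_arm
    group = np.repeat([0, 1], n_per_arm)
    rate = baseline_rate_per_month * np.where(group == 1, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0.0, censoring_max_months, n)
    return pd.DataFrame(
        {
            "group": group,
            "followup_months": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
        }
    )
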