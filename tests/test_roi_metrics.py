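"""Mask downsampling, volume/AAC/SUV indices and IBW normalization."""

import numpy as np
import pytest

from psoaspet import (
    BinaryMask3D,
    InputError,
    Modality,
    VolumeGrid,
    average_attenuation,
    downsample_mask_to_pet,
    ideal_body_weight,
    liver_reference,
    masked_volume,
    myocardial_metrics,
    normalize_volume,
    normalized_suv,
    psoas_metrics,
    vc_suv,
)
from psoaspet.roi_metrics import coverage_fractions


def grid(shape, spacing, origin=(0, 0, 0), modality=Modality.CT_HU, fill=0.0):
    return VolumeGrid(np.full(shape, float(fill)), spacing, origin, modality)


def brute_force_coverage(mask, ct, pet):
    """O(N_ct * N_pet) physical box-overlap oracle."""
    out = np.zeros(pet.shape)
    ct_idx = np.argwhere(mask)
    for pz in range(pet.shape[0]):
        for py in range(pet.shape[1]):
            for px in range(pet.shape[2]):
                p_lo = [pet.voxel_centers(a)[i] - pet.spacing_mm[a] / 2
                        for a, i in zip(range(3), (pz, py, px))]
                p_hi = [lo + pet.spacing_mm[a] for a, lo in enumerate(p_lo)]
                vol = 0.0
                for cz, cy, cx in ct_idx:
                    c_lo = [ct.voxel_centers(a)[i] - ct.spacing_mm[a] / 2
                            for a, i in zip(range(3), (cz, cy, cx))]
                    ov = 1.0
                    for a in range(3):
                        ov *= max(0.0, min(c_lo[a] + ct.spacing_mm[a], p_hi[a]) - max(c_lo[a], p_lo[a]))
                    vol += ov
                out[pz, py, px] = vol / pet.voxel_volume_mm3
    return out


class TestDownsampleMask:
    def test_full_coverage_included(self):
        ct = grid((2, 4, 4), (1, 1, 1))
        pet = grid((1, 2, 2), (2, 2, 2), origin=(0.5, 0.5, 0.5), modality=Modality.PET_SUV)
        labels = np.zeros((2, 4, 4), np.uint8)
        labels[:, :2, :2] = 1  # exactly tiles PET voxel (0,0,0)
        out = downsample_mask_to_pet(BinaryMask3D(labels), ct, pet)
        assert out.labels[0, 0, 0] == 1
        assert out.count() == 1

    def test_quarter_coverage_excluded_at_half_threshold(self):
        ct = grid((2, 4, 4), (1, 1, 1))
        pet = grid((1, 2, 2), (2, 2, 2), origin=(0.5, 0.5, 0.5), modality=Modality.PET_SUV)
        labels = np.zeros((2, 4, 4), np.uint8)
        labels[:, 0, 0] = 1  # 2 of 8 CT voxels in the PET box
        out = downsample_mask_to_pet(BinaryMask3D(labels), ct, pet, frac_threshold=0.5)
        assert out.count() == 0
        out2 = downsample_mask_to_pet(BinaryMask3D(labels), ct, pet, frac_threshold=0.25)
        assert out2.labels[0, 0, 0] == 1

    def test_matches_brute_force_oracle_on_toy_grids(self):
        rng = np.random.default_rng(17)
        ct = grid((10, 10, 10), (1, 1, 1))
        pet = grid((5, 5, 5), (2, 2, 2), origin=(0.7, 0.3, 0.5), modality=Modality.PET_SUV)
        labels = (rng.uniform(size=(10, 10, 10)) < 0.4).astype(np.uint8)
        labels[labels > 0] = rng.integers(1, 3, int((labels > 0).sum()))
        mask = BinaryMask3D(labels)
        for side in (1, 2):
            fast = coverage_fractions(labels == side, ct, pet)
            slow = brute_force_coverage(labels == side, ct, pet)
            np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_monotone_in_threshold(self, small_phantom):
        _, ct, pet, truth, _ = small_phantom
        prev = None
        for thr in (0.3, 0.5, 0.7, 0.9):
            m = downsample_mask_to_pet(truth.ct_mask, ct, pet, frac_threshold=thr)
            if prev is not None:
                assert np.all((m.labels > 0) <= (prev.labels > 0))
            prev = m

    def test_volume_approximately_conserved(self, small_phantom):
        _, ct, pet, truth, _ = small_phantom
        m = downsample_mask_to_pet(truth.ct_mask, ct, pet, frac_threshold=0.5)
        v_ct = masked_volume(truth.ct_mask, ct)
        v_pet = masked_volume(m, pet)
        assert abs(v_pet - v_ct) / v_ct < 0.15


class TestMaskedVolume:
    def test_unit_cubes(self):
        labels = np.zeros((10, 10, 10), np.uint8)
        labels.ravel()[:1000] = 1
        assert masked_volume(BinaryMask3D(labels), grid((10, 10, 10), (1, 1, 1))) == pytest.approx(1.0)

    def test_empty_mask(self):
        labels = np.zeros((4, 4, 4), np.uint8)
        assert masked_volume(BinaryMask3D(labels), grid((4, 4, 4), (1, 1, 1))) == 0.0

    def test_anisotropic_voxels(self):
        labels = np.zeros((8, 10, 10), np.uint8)
        labels.ravel()[:500] = 1
        assert masked_volume(BinaryMask3D(labels), grid((8, 10, 10), (3, 1, 1))) == pytest.approx(1.5)

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(2)
        g = grid((6, 6, 6), (2, 1, 1))
        lab = rng.integers(0, 3, (6, 6, 6)).astype(np.uint8)
        total = masked_volume(BinaryMask3D(lab), g)
        left = masked_volume(BinaryMask3D((lab == 1).astype(np.uint8)), g)
        right = masked_volume(BinaryMask3D(((lab == 2) * 2).astype(np.uint8)), g)
        assert total == pytest.approx(left + right)


class TestAttenuation:
    def test_uniform_region(self):
        ct = grid((4, 4, 4), (1, 1, 1), fill=40.0)
        lab = np.zeros((4, 4, 4), np.uint8)
        lab[1:3] = 1
        assert average_attenuation(ct, BinaryMask3D(lab)) == 40.0

    def test_two_level_mean(self):
        ct = grid((2, 2, 2), (1, 1, 1))
        ct.data[0] = 30.0
        ct.data[1] = 50.0
        lab = np.ones((2, 2, 2), np.uint8)
        assert average_attenuation(ct, BinaryMask3D(lab)) == 40.0

    def test_empty_mask_error(self):
        ct = grid((2, 2, 2), (1, 1, 1))
        with pytest.raises(InputError):
            average_attenuation(ct, BinaryMask3D(np.zeros((2, 2, 2), np.uint8)))


class TestSuvIndices:
    def _uniform(self, value, liver=2.0):
        pet = grid((4, 4, 4), (3, 4, 4), modality=Modality.PET_SUV, fill=value)
        lab = np.zeros((4, 4, 4), np.uint8)
        lab[1:3, 1:3, 1:3] = 1
        return pet, BinaryMask3D(lab), liver

    def test_n_suv_hand_value(self):
        pet, mask, liver = self._uniform(0.9)
        suv_mean, n_suv = normalized_suv(pet, mask, liver)
        assert suv_mean == pytest.approx(0.9)
        assert n_suv == pytest.approx(0.45)

    def test_identity_normalizer(self):
        pet, mask, _ = self._uniform(0.7)
        suv_mean, n_suv = normalized_suv(pet, mask, 1.0)
        assert n_suv == suv_mean

    def test_scale_invariance_with_recomputed_liver(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0.5, 1.5, (4, 4, 4))
        lab = np.zeros((4, 4, 4), np.uint8)
        lab[1:3] = 1
        for k in (1.0, 3.7):
            pet = VolumeGrid(k * data, (3, 4, 4), modality=Modality.PET_SUV)
            liver = float(pet.data[0].mean())
            _, n = normalized_suv(pet, BinaryMask3D(lab), liver)
            if k == 1.0:
                base = n
        assert n == pytest.approx(base, rel=1e-12)

    def test_vc_suv_hand_value(self):
        pet = grid((1, 1, 3), (3, 4, 4), modality=Modality.PET_SUV)
        pet.data[0, 0] = [0.4, 0.5, 0.6]
        mask = BinaryMask3D(np.ones((1, 1, 3), np.uint8))
        # sample SD 0.1 over mean 0.5
        assert vc_suv(pet, mask, 1.0) == pytest.approx(20.0)

    def test_vc_suv_uniform_is_zero(self):
        pet, mask, liver = self._uniform(0.9)
        assert vc_suv(pet, mask, liver) == 0.0

    def test_vc_suv_same_on_suv_and_n_suv(self):
        rng = np.random.default_rng(5)
        pet = VolumeGrid(rng.uniform(0.2, 1.4, (4, 4, 4)), (3, 4, 4), modality=Modality.PET_SUV)
        lab = np.zeros((4, 4, 4), np.uint8)
        lab[:2] = 2
        mask = BinaryMask3D(lab)
        assert vc_suv(pet, mask, 1.0) == pytest.approx(vc_suv(pet, mask, 2.31), rel=1e-12)

    def test_errors(self):
        pet, mask, _ = self._uniform(0.9)
        with pytest.raises(InputError):
            normalized_suv(pet, mask, 0.0)
        with pytest.raises(InputError):
            vc_suv(pet, mask, -1.0)


class TestLiverReference:
    def test_uniform_liver(self):
        pet = grid((4, 4, 4), (3, 4, 4), modality=Modality.PET_SUV, fill=2.0)
        lab = np.zeros((4, 4, 4), np.uint8)
        lab[1:3] = 1
        assert liver_reference(pet, liver_mask=BinaryMask3D(lab)) == 2.0

    def test_sphere_on_phantom_within_one_percent(self, small_phantom):
        spec, ct, pet, truth, meta = small_phantom
        from psoaspet import compute_suv

        pet_suv = compute_suv(pet, meta)
        # sphere must fit inside the miniature liver (z semi-axis 6 mm)
        got = liver_reference(pet_suv, sphere=(spec.liver_center_mm, 10.0))
        assert got == pytest.approx(spec.liver_suv_mean, rel=0.01)

    def test_empty_region_error(self):
        pet = grid((4, 4, 4), (3, 4, 4), modality=Modality.PET_SUV, fill=2.0)
        with pytest.raises(InputError):
            liver_reference(pet, sphere=((-500.0, -500.0, -500.0), 10.0))
        with pytest.raises(InputError):
            liver_reference(pet)


class TestMyocardium:
    def _lv(self, n_slices, suv=3.0):
        # 1 mL voxels: n_slices * 4 voxels = volume in mL
        pet = grid((6, 4, 4), (10, 10, 10), modality=Modality.PET_SUV, fill=suv)
        lab = np.zeros((6, 4, 4), np.uint8)
        lab[:n_slices, 0, :] = 1
        return pet, BinaryMask3D(lab)

    def test_hand_value(self):
        pet, lv = self._lv(3)  # 12 mL
        m = myocardial_metrics(pet, lv, liver_suv_mean=2.0)
        assert m.n_suv == pytest.approx(1.5)
        assert m.volume_mL == pytest.approx(12.0)

    def test_small_voi_rejected(self):
        pet, lv = self._lv(2)  # 8 mL
        with pytest.raises(InputError, match="minimum"):
            myocardial_metrics(pet, lv, liver_suv_mean=2.0)

    def test_identity_when_liver_equals_uptake(self):
        pet, lv = self._lv(3, suv=2.0)
        assert myocardial_metrics(pet, lv, liver_suv_mean=2.0).n_suv == pytest.approx(1.0)


class TestIdealBodyWeight:
    @pytest.mark.parametrize(
        "sex, height_cm, expected",
        [
            ("male", 177.8, 71.0),       # 70 in -> 52 + 1.9 * 10
            ("female", 152.4, 49.0),     # 60 in base case
            ("female", 147.0, 49.0),     # below 60 in floors at base
            ("male", 182.88, 71.0 + 1.9 * 2),
        ],
    )
    def test_robinson_formula(self, sex, height_cm, expected):
        assert ideal_body_weight(sex, height_cm) == pytest.approx(expected, abs=1e-9)

    def test_normalized_volume(self):
        assert normalize_volume(284.0, 71.0) == pytest.approx(4.0)

    def test_unknown_sex_rejected(self):
        with pytest.raises(InputError):
            ideal_body_weight("other", 170.0)


class TestPipelineDeterminism:
    def test_psoas_metrics_bit_identical(self, small_phantom):
        spec, ct, pet, truth, meta = small_phantom
        from psoaspet import compute_suv

        pet_suv = compute_suv(pet, meta)
        runs = [
            psoas_metrics(ct, pet_suv, truth.ct_mask, spec.liver_suv_mean,
                          sex=meta.sex, height_cm=meta.height_cm)
            for _ in range(2)
        ]
        assert runs[0] == runs[1]
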