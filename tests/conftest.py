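"""Shared fixtures: small phantoms sized for fast unit tests."""

import numpy as np
import pytest

from psoaspet import (
    PhantomSpec,
    SegmentationConfig,
    default_segmentation_seeds,
    generate_phantom,
)


def small_spec(**overrides) -> PhantomSpec:
    """A 96 x 96 x 12 CT / 24 x 24 x 12 PET phantom for fast tests."""
    defaults = dict(
        ct_shape=(12, 96, 96),
        ct_spacing_mm=(3.0, 1.0, 1.0),
        pet_shape=(12, 24, 24),
        pet_spacing_mm=(3.0, 4.0, 4.0),
        pet_origin_shift_mm=(0.0, 1.0, 1.0),
        muscle_center_offset_mm=(5.0, 22.0),
        muscle_semi_axes_mm=(12.0, 9.0),
        muscle_slice_range=(1, 11),
        vertebra_half_width_mm=8.0,
        liver_center_mm=(9.0, 20.0, 20.0),
        liver_semi_axes_mm=(6.0, 12.0, 12.0),
        ct_noise_sd_hu=0.0,
        pet_noise_sd_suv=0.0,
        seed=11,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    spec = small_spec()
    ct, pet, truth, meta = generate_phantom(spec)
    return spec, ct, pet, truth, meta


@pytest.fixture(scope="session")
def small_config(small_phantom):
    spec = small_phantom[0]
    return SegmentationConfig(
        slice_start=spec.muscle_slice_range[0],
        slice_stop=spec.muscle_slice_range[1],
        seeds=default_segmentation_seeds(spec),
        search_radius_px=25.0,
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.sum(a & b) / (a.sum() + b.sum())
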