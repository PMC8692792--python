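"""Shared phantoms for the test suite (all generated at test time)."""

import warnings

import numpy as np
import pytest

import lungmorph as lm


def make_foam(**kwargs):
    """Generate a foam, swallowing saturation warnings where intended."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", lm.SaturationWarning)
        return lm.generate_sphere_foam(lm.PhantomSpec(**kwargs))


@pytest.fixture(scope="session")
def foam64():
    """64^3-voxel uniform foam (256 μm box, 40 μm cavities, phi 0.35)."""
    return make_foam(box_um=256.0, target_porosity=0.35, seed=5)


@pytest.fixture(scope="session")
def foam150():
    """150^3-voxel uniform foam (600 μm box) for map-scale checks."""
    return make_foam(box_um=600.0, target_porosity=0.35, seed=6)


@pytest.fixture(scope="session")
def foam_tall():
    """Elongated foam (600 x 1600 x 600 μm) hosting zone-wise RVE selection."""
    return make_foam(box_um=(600.0, 1600.0, 600.0), target_porosity=0.35, seed=4)


@pytest.fixture(scope="session")
def sphere60():
    """Digitized single sphere, r = 60 μm, centred in a 240 μm cube."""
    return lm.digitize_spheres(240.0, 4.0, [[120.0, 120.0, 120.0]], [60.0])


@pytest.fixture(scope="session")
def ct_phantom(foam64):
    """CT-like rendering of foam64 (levels 50/200, 4 μm PSF, noise σ 15)."""
    mask, truth = foam64
    vol = lm.apply_ct_appearance(mask, 50.0, 200.0, psf_sigma_um=4.0,
                                 noise_sigma=15.0, seed=10)
    return vol, mask
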