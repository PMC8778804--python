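import numpy as np
import pytest

from ctinertia.calibration import apply_calibration, fit_calibration, sample_phantom
from ctinertia.inertial import build_mass_model
from ctinertia.segmentation import apply_threshold
from ctinertia.synthetic import make_bird_study, rasterize_scene
from ctinertia._util import AIR_DENSITY

# test-scale scene: physically identical bird, half in-plane resolution of a
# clinical scan, so rasterisation stays ~1M voxels
TEST_SHAPE = (64, 256, 256)
TEST_SPACING = (1.25, 1.96, 1.96)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def bird_study():
    """Rasterised bird scene with fixtures, plus ROIs and ground truth."""
    scene, rois, air_roi, densities = make_bird_study(
        spacing=TEST_SPACING, volume_shape=TEST_SHAPE, noise_sigma=5.0, seed=7
    )
    grid, labels, truth = rasterize_scene(scene)
    return {
        "scene": scene,
        "grid": grid,
        "labels": labels,
        "truth": truth,
        "rois": rois,
        "air_roi": air_roi,
        "densities": densities,
    }


@pytest.fixture(scope="session")
def bird_calibration(bird_study):
    samples = [
        sample_phantom(bird_study["grid"], roi_list, rho, name)
        for (name, roi_list), rho in zip(
            bird_study["rois"].items(), bird_study["densities"]
        )
    ]
    air = sample_phantom(bird_study["grid"], bird_study["air_roi"], AIR_DENSITY, "air")
    return fit_calibration(samples, air_sample=air)


@pytest.fixture(scope="session")
def bird_model(bird_study, bird_calibration):
    """Mass model of the specimen at a grey threshold between air and tissue."""
    grid, labels = bird_study["grid"], bird_study["labels"]
    mask = apply_threshold(grid, 1100.0, exclusion_mask=labels.labels >= 100)
    density = apply_calibration(grid, bird_calibration)
    return build_mass_model(density, mask)
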