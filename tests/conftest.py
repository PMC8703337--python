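import numpy as np
import pytest

from seedspectra.calibration import calibrate, trim_bands
from seedspectra.envi import Hypercube
from seedspectra.segmentation import SegmentationParams, segment_scene
from seedspectra.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One desk-scale scene: (raw cube, references, ground truth)."""
    return generate_scene(SceneSpec(rng_seed=42))


@pytest.fixture(scope="session")
def overlap_scene():
    """Scene with two forced overlapping seed pairs."""
    return generate_scene(
        SceneSpec(rng_seed=11, overlap_fraction=0.2, n_overlapping_pairs=2)
    )


@pytest.fixture(scope="session")
def desk_params():
    return SegmentationParams(min_pixels=50, rng_seed=0)


@pytest.fixture(scope="session")
def segmented_scene(small_scene, desk_params):
    """Calibrated + trimmed cube and the recovered seed mask."""
    raw, refs, truth = small_scene
    cube, window = trim_bands(calibrate(raw, refs))
    mask = segment_scene(raw, desk_params)
    return cube, window, mask, truth


def make_cube(shape=(4, 5, 3), dtype=np.uint16, seed=0, interleave="bil"):
    rng = np.random.default_rng(seed)
    if np.issubdtype(dtype, np.integer):
        data = rng.integers(0, 4000, size=shape).astype(dtype)
    else:
        data = rng.random(shape).astype(dtype)
    return Hypercube(
        data=data,
        wavelengths_nm=np.linspace(600, 1700, shape[2]),
        interleave=interleave,
        dtype_code=12 if np.issubdtype(dtype, np.integer) else 4,
    )
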