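import numpy as np
import pytest

from vesselforge import BinaryMask, ImageVolume, PhantomSpec, generate_phantom


@pytest.fixture
def small_volume() -> ImageVolume:
    rng = np.random.default_rng(7)
    data = rng.normal(80.0, 10.0, size=(8, 9, 10))
    return ImageVolume(data=data, spacing=(0.5, 0.586, 0.586), origin=(1.0, -2.0, 3.0))


@pytest.fixture
def tube_spec() -> PhantomSpec:
    """Straight 3 mm radius tube, 40 mm long, isotropic 1 mm voxels."""
    return PhantomSpec(
        grid_shape=(16, 16, 56),
        spacing=(1.0, 1.0, 1.0),
        centerline=((8.0, 8.0, 8.0), (8.0, 8.0, 48.0)),
        vessel_radius_mm=3.0,
        aneurysm_center=(8.0, 8.0, 28.0),
        aneurysm_diameter_mm=8.0,
        lumen_peak_hu=336.0,
    )


@pytest.fixture
def tube_phantom(tube_spec):
    return generate_phantom(tube_spec)


def random_mask(rng: np.random.Generator, shape=(6, 7, 8), p=0.3) -> BinaryMask:
    occ = rng.random(shape) < p
    vol = ImageVolume(np.zeros(shape), spacing=(1.0, 1.0, 1.0))
    return BinaryMask.from_bool(occ, like=vol)
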