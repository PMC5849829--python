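import numpy as np
import pytest

from regsurrogate.image_model import VolumetricImage
from regsurrogate.phantom import PhantomSpec, generate_subject

# scaled-down anatomy for fast tests: 64 x 64 x 64 mm field of view
SMALL_ORGANS = {
    "body": ((32.0, 32.0, 31.0), (30.0, 27.0, 30.0)),
    "bladder": ((32.0, 21.0, 39.0), (11.0, 9.0, 10.0)),
    "rectum": ((32.0, 48.0, 32.0), (5.0, 5.0, 18.0)),
    "prostate": ((32.0, 34.0, 29.0), (10.0, 9.0, 9.0)),
    "seminal_vesicles": ((32.0, 41.0, 38.0), (8.0, 4.0, 3.5)),
    "penile_bulb": ((32.0, 37.0, 15.0), (5.0, 4.5, 3.5)),
}


def small_spec(seed: int, **overrides) -> PhantomSpec:
    """A coarse, quick-to-generate phantom for unit tests."""
    organs = dict(SMALL_ORGANS)
    kwargs = dict(
        seed=seed,
        shape=(33, 33, 33),
        spacing=(2.0, 2.0, 2.0),
        organs=organs,
        fiducial_radius_mm=5.0,
        boundary_smooth_mm=1.0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def default_subject():
    """One full-size phantom subject, shared across the session."""
    return generate_subject(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def small_subject():
    return generate_subject(small_spec(seed=3), bumps=4, amplitude_mm=3.0, scale_mm=14.0)


@pytest.fixture
def smooth_image():
    """A smooth analytic test image on an anisotropic grid."""
    geom = VolumetricImage(np.zeros((24, 24, 16)), (1.25, 1.25, 2.5), (0.0, 0.0, 0.0))
    x = geom.physical_grid()
    geom.voxels = (
        100.0 * np.sin(x[..., 0] / 7.0) * np.cos(x[..., 1] / 9.0)
        + 40.0 * np.sin(x[..., 2] / 11.0)
    )
    return geom
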