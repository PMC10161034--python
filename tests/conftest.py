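import numpy as np
import pytest

from adipoct.core import VolumeGeometry
from adipoct.phantom import PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def geometry():
    """Small grid that still resolves every phantom layer."""
    return VolumeGeometry(
        n_slices=2,
        n_rows=192,
        n_cols=192,
        pixel_spacing=2.5,
        slice_thickness=5.25,
        slice_interval=5.0,
        fov_diameter=480.0,
    )


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom(default_spec, geometry):
    """(volume, mask, truth) for the default spec; treat as read-only."""
    return build_phantom(default_spec, geometry)


@pytest.fixture(scope="session")
def flat_spec():
    """Piecewise-constant phantom (no HU texture)."""
    return PhantomSpec(hu_jitter=0.0)


@pytest.fixture(scope="session")
def flat_phantom(flat_spec, geometry):
    return build_phantom(flat_spec, geometry)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
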