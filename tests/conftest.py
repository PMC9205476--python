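import numpy as np
import pytest

from rectalseg.phantom import PhantomSpec, generate_phantom


def tiny_spec(**overrides) -> PhantomSpec:
    """A small, fast phantom: 32x32x10 voxels at 1x1x3 mm."""
    base = dict(
        grid_shape=(32, 32, 10),
        spacing_mm=(1.0, 1.0, 3.0),
        lumen_radius_mm=2.5,
        wall_thickness_mm=2.0,
        mesorectum_radius_mm=10.0,
        tumor_angular_extent_deg=120.0,
        tumor_length_mm=14.0,
        invasion_depth_mm=-1.0,
        noise_sigma=5.0,
        seed=7,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture
def t2_case():
    return generate_phantom(tiny_spec(invasion_depth_mm=-1.0))


@pytest.fixture
def t3_case():
    return generate_phantom(tiny_spec(invasion_depth_mm=3.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
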