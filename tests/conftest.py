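import numpy as np
import pytest

from swiveins import PhantomSpec, Volume, generate_phantom, symmetric_affine


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Reduced grid for fast unit tests (not the default study conditions)."""
    return PhantomSpec(shape=(48, 56, 40), brain_radii_mm=(19.0, 23.0, 16.0),
                       n_veins_left=8, n_veins_right=5, seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture()
def symmetric_grid() -> Volume:
    shape = (20, 24, 16)
    return Volume(np.zeros(shape), symmetric_affine(shape))


@pytest.fixture()
def ellipsoid_mask(symmetric_grid) -> Volume:
    g = symmetric_grid
    d2 = sum((g.world_coords(axis=k) / r) ** 2
             for k, r in enumerate((8.0, 10.0, 6.0)))
    return g.like((d2 <= 1.0).astype(np.uint8))
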