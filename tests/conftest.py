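import numpy as np
import pytest

from sphsurv.harmonics import SphericalGrid
from sphsurv.phantoms import PhantomCohortSpec, generate_mask


@pytest.fixture(scope="session")
def grid16():
    return SphericalGrid(16)


@pytest.fixture(scope="session")
def grid8():
    return SphericalGrid(8)


@pytest.fixture(scope="session")
def ball_mask():
    """Voxelized ball of radius 8 mm at 1 mm spacing, with its solid."""
    spec = PhantomCohortSpec(
        n_subjects=2, r0_range=(8.0, 8.0), perturbation_scale=0.0, seed=1
    )
    return generate_mask(spec, 0)


@pytest.fixture(scope="session")
def star_phantoms():
    """20 random star-shaped phantoms (mask, solid) at default settings."""
    spec = PhantomCohortSpec(n_subjects=20, seed=5)
    return [generate_mask(spec, i) for i in range(20)]
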