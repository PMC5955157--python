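from dataclasses import replace

import numpy as np
import pytest

from petsubvol.image_io import SuvImage, VolumeGrid
from petsubvol.synthetic_phantom import default_patient_config, generate_patient


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_grid():
    return VolumeGrid(shape=(16, 16, 16), spacing=(4.0, 4.0, 4.0), origin=(-30.0, -30.0, -30.0))


@pytest.fixture(scope="session")
def default_phantom():
    """One representative recurrence phantom at default noise."""
    return generate_patient(default_patient_config(seed=1))


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Same phantom without noise (exact construction checks)."""
    return generate_patient(replace(default_patient_config(seed=1), noise_sd=0.0))


def random_suv_image(rng, grid, scale=10.0):
    vals = rng.uniform(0.0, scale, grid.shape).astype(np.float32)
    return SuvImage(grid, vals, "PET")
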