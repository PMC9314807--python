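import numpy as np
import pytest
from hypothesis import settings

from oriqsm import PhantomSpec, simulate_study

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless cylinder-in-agar phantom at the 10-rotation specimen geometry.

    Desk-scale version of the default phantom (48^3 grid, radius 3, length 24)
    with the generator parameters kept at the package defaults.  Unit
    responses are cached on the ground truth for reuse across tests.
    """
    spec = PhantomSpec(grid_shape=(48, 48, 48), radius_voxels=3.0,
                       length_voxels=24.0, seed=7)
    study, model, truth = simulate_study(spec, keep_responses=True)
    return spec, study, model, truth


@pytest.fixture(scope="session")
def whole_brain_b0s():
    from oriqsm import make_orientation_set

    return make_orientation_set("whole_brain")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
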