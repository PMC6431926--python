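import numpy as np
import pytest

from helibundle.model_core import ModelParams
from helibundle.structure_analysis import (make_bundle, make_ideal_helix,
                                           make_random_coil, make_rod)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def helix20(params):
    return make_ideal_helix(20, params)


@pytest.fixture(scope="session")
def helix30(params):
    return make_ideal_helix(30, params)


@pytest.fixture(scope="session")
def hairpin30(params):
    """Two 13-monomer helices joined by a 4-monomer turn (N = 30)."""
    return make_bundle(2, 13, params, turn_monomers=4)


@pytest.fixture(scope="session")
def bundle3(params):
    return make_bundle(3, 10, params, turn_monomers=3)


@pytest.fixture(scope="session")
def rod10(params):
    return make_rod(10, params)


@pytest.fixture()
def coil30(params):
    return make_random_coil(30, params, np.random.default_rng(1234))


def random_rigid_motion(pos, rng):
    """Random proper rotation + translation (test helper)."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return pos @ R.as_matrix().T + rng.normal(scale=5.0, size=3)
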