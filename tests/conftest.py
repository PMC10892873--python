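import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spinemotion.kinematics import load_chain


@pytest.fixture(scope="session")
def cervical():
    return load_chain("cervical")


@pytest.fixture(scope="session")
def lumbar():
    return load_chain("lumbar")


@pytest.fixture(scope="session")
def chains(cervical, lumbar):
    return {"cervical": cervical, "lumbar": lumbar}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotations(n: int, seed: int = 0) -> Rotation:
    return Rotation.random(n, rng=np.random.default_rng(seed))
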