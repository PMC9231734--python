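import numpy as np
import pytest

from fluoropose.geometry import CameraModel
from fluoropose.synthetic import generate_toy_implant_pair


@pytest.fixture(scope="session")
def combo():
    return generate_toy_implant_pair(seed=7)


@pytest.fixture(scope="session")
def cam64():
    return CameraModel.standard(64)


@pytest.fixture(scope="session")
def cam128():
    return CameraModel.standard(128)


@pytest.fixture(scope="session")
def cam256():
    return CameraModel.standard(256)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
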