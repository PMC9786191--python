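import numpy as np
import pytest

from poremcm import (
    EnergyParams,
    SyntheticChannelSpec,
    make_toy_channel,
    make_toy_ligand,
)


@pytest.fixture(scope="session")
def toy_channel():
    return make_toy_channel()


@pytest.fixture(scope="session")
def mex():
    return make_toy_ligand()


@pytest.fixture()
def params():
    return EnergyParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
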