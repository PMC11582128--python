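import numpy as np
import pytest

from fatfrac import (
    FatSpectrumModel,
    FwsConfig,
    make_calf_phantom,
    make_vial_phantom,
    protocol_preset,
)


@pytest.fixture(scope="session")
def phantom_model():
    return FatSpectrumModel.named("peanut_oil_phantom_9peak")


@pytest.fixture(scope="session")
def invivo_model():
    return FatSpectrumModel.named("subcutaneous_invivo_8peak")


@pytest.fixture(scope="session")
def single_peak():
    return FatSpectrumModel.single_peak(-3.3)


@pytest.fixture(scope="session")
def proto_7t_high():
    return protocol_preset("7T-highNSA")


@pytest.fixture(scope="session")
def proto_7t_low():
    return protocol_preset("7T-lowNSA")


@pytest.fixture(scope="session")
def vial_phantom_small():
    return make_vial_phantom(grid_size=48)


@pytest.fixture(scope="session")
def calf_phantom_small():
    return make_calf_phantom(grid_size=48)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def fws_config(phantom_model):
    return FwsConfig(fat_model=phantom_model)
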