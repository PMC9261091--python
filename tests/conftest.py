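import numpy as np
import pytest

from assrnet.cells import build_basket, build_l5pc
from assrnet.channels import load_channel_table
from assrnet.cells import data_path


@pytest.fixture(scope="session")
def l5pc():
    return build_l5pc()


@pytest.fixture(scope="session")
def basket():
    return build_basket()


@pytest.fixture(scope="session")
def l5pc_channels():
    return load_channel_table(data_path("channels_l5pc.tsv"))


@pytest.fixture(scope="session")
def fs_channels():
    return load_channel_table(data_path("channels_fs.tsv"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
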