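import logging

import numpy as np
import pytest

from audpath.fmri_design import BlockParadigm
from audpath.synthetic_data import SimConfig, small_config

logging.getLogger("audpath").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def paradigm():
    return BlockParadigm()


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def fast_config():
    return small_config(seed=42)
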