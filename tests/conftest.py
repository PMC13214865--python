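import numpy as np
import pytest

from hcpval.core import default_design
from hcpval.simulate import SyntheticTruth, gen_replicate_blocks


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture()
def truth():
    return SyntheticTruth(seed=7)


@pytest.fixture()
def blocks(design, truth):
    return gen_replicate_blocks(design, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
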