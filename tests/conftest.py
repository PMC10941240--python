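import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ocumsi import design as dsg
from ocumsi.simulate import SimParams


@pytest.fixture(scope="session")
def pool():
    return dsg.build_frequency_pool()


@pytest.fixture(scope="session")
def session_exp1():
    return dsg.build_session(1, rng_seed=0)


@pytest.fixture(scope="session")
def session_exp2():
    return dsg.build_session(2, rng_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_params():
    return SimParams()
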