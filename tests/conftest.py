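import numpy as np
import pytest

from normevol.fixtures import nymphalid_fixture


@pytest.fixture(scope="session")
def fixture_data():
    return nymphalid_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
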