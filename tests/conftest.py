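import numpy as np
import pytest

from okit import synthetic


@pytest.fixture(scope="session")
def chloro_truth():
    return synthetic.make_quadripartite_genome(lsc_len=12000, ssc_len=5000, ir_len=3000, seed=11)


@pytest.fixture(scope="session")
def default_fixture():
    return synthetic.default_fixture(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
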