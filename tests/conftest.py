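import numpy as np
import pytest

from karyomc.chain_models import ChainParams, load_score_table


@pytest.fixture(scope="session")
def score_table():
    return load_score_table()


@pytest.fixture()
def basic_params():
    return ChainParams(N=8, p=0.0025, mu=1.0, C=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
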