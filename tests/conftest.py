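import numpy as np
import pytest

import frsa


@pytest.fixture(scope="session")
def continuum():
    return frsa.make_condition_continuum()


@pytest.fixture(scope="session")
def models(continuum):
    return frsa.categorical_model_set(len(continuum))


@pytest.fixture(scope="session")
def acoustic(continuum):
    return frsa.acoustic_rsm(continuum)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
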