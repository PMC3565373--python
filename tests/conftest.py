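import numpy as np
import pytest

from memphase.meanfield import ExactLimitEOS, MeanFieldEOS


@pytest.fixture(scope="session")
def mf_eos():
    return MeanFieldEOS()


@pytest.fixture(scope="session")
def exact_eos():
    return ExactLimitEOS()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
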