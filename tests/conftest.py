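import numpy as np
import pytest

from allokair.parameters import KineticParameters
from allokair.synthetic import GeneratorSpec


@pytest.fixture
def params() -> KineticParameters:
    return KineticParameters()


@pytest.fixture
def quench_params() -> KineticParameters:
    return KineticParameters(N_total=10.0)


@pytest.fixture
def noiseless_spec() -> GeneratorSpec:
    return GeneratorSpec(channel_noise_sd=0.0, jitter_rel_sd=0.0, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
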