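import numpy as np
import pytest

from barn_cgwo.synthetic_barn import GeneratorConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_table():
    """A 300-row clean synthetic sensor table shared across tests."""
    return generate(GeneratorConfig(n_rows=300, seed=7))
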