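import numpy as np
import pytest

from m6afgk import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """120-record planted-motif corpus, cheap enough for repeated CV."""
    return generate_corpus(
        SyntheticConfig(n_pos=60, n_neg=60, plant_rate=0.9, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
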