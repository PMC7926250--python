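import numpy as np
import pytest

from ximark import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return simulate.SimConfig(
        seed=42,
        chromosomes=(("cX", 60_000), ("c1", 40_000)),
        library_size=4_000,
        window_width=10_000,
    )


@pytest.fixture
def small_genome(small_config):
    rng = np.random.default_rng(small_config.seed)
    return simulate.simulate_genome(small_config, rng)
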