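import numpy as np
import pytest

import nmfuse as nm


@pytest.fixture(scope="session")
def tiny_config():
    """Small architecture for fast unit tests (not the study defaults)."""
    return nm.ModelConfig(n_kernels=8, embed_dim=8, n_heads=2, fc_hidden=8)


@pytest.fixture(scope="session")
def small_dataset():
    """120 windows with a strong planted motif, all three views encoded."""
    spec = nm.SynthSpec(n_per_class=60, seed=5)
    return nm.encode_dataset(nm.generate(spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
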