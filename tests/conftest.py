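import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """24 small synthetic scenes shared by pipeline-level tests."""
    from frcnet.synthetic import SynthConfig, generate_sample

    cfg = SynthConfig(n_images=24, size=64, seed=11)
    pairs = [generate_sample(cfg, i) for i in range(cfg.n_images)]
    X = np.stack([p.image for p in pairs])
    y = np.stack([p.mask for p in pairs])
    return X, y
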