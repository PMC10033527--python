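import numpy as np
import pytest

from eards.data import SyntheticConfig, generate_synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synthetic_128():
    """One deterministic 128x128 synthetic fundus image with ground truth."""
    cfg = SyntheticConfig(size=128, disc_semi_axes=(26.0, 28.0),
                          cup_semi_axes=(11.0, 12.0), center_jitter=8.0, seed=3)
    image, mask, true_cdr = generate_synthetic(cfg)
    return image, mask, true_cdr
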