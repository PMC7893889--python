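import numpy as np
import pytest

from fidburn import PhantomConfig, generate_phantom
from fidburn.volume import ImageVolume


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless 4-marker phantom on the Dixon grid (shared, read-only)."""
    cfg = PhantomConfig(seed=7)
    mr, sct, truth = generate_phantom(cfg)
    return cfg, mr, sct, truth


@pytest.fixture()
def flat_volume():
    """Constant-intensity volume on the anisotropic Dixon grid."""
    return ImageVolume(np.full((20, 20, 16), 100.0), spacing=(1.7, 1.7, 2.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
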