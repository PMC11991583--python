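import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lgwheatnet.data_io import SyntheticSceneConfig, generate_synthetic_dataset


@pytest.fixture(scope="session")
def small_scenes():
    """Eight deterministic 128-px synthetic canopy scenes."""
    cfg = SyntheticSceneConfig(image_size=128, spikes_per_image=(2, 5), seed=11)
    return generate_synthetic_dataset(cfg, 8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
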