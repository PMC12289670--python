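import numpy as np
import pytest

from strawdet import ModelConfig, build_model
from strawdet.scenes import make_dataset


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small low-resolution synthetic dataset shared across tests."""
    root = tmp_path_factory.mktemp("tinyset")
    return make_dataset(12, seed=11, out_dir=root, image_size=64,
                        objects_per_image=(1, 2), depth_range_cm=(8, 20))


@pytest.fixture(scope="session")
def tiny_model():
    """Small 4-class detector (untrained)."""
    return build_model(ModelConfig(scale="n", num_classes=4), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
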