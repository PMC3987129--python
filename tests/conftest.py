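import numpy as np
import pytest

from bebkit import demo as demo_mod
from bebkit.repository import create_bundle


@pytest.fixture
def bundle(tmp_path):
    return create_bundle(tmp_path, "exp")


@pytest.fixture(scope="session")
def demo_result(tmp_path_factory):
    """One small correlative demo bundle shared by read-only tests."""
    out = tmp_path_factory.mktemp("demo")
    params = demo_mod.DemoParams(seed=7, n_frames=3, image_size=32, n_em_images=2)
    return demo_mod.generate_demo_bundle(params, out)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
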