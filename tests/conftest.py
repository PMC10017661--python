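import numpy as np
import pytest

from ssoptools import build_lut, make_bowel_scene


@pytest.fixture(scope="session")
def default_lut():
    """Default 64x64 diffusion-engine LUT at fx_pair (0, 0.2)."""
    return build_lut()


@pytest.fixture(scope="session")
def bowel_scene():
    """Default-truth bowel scene at reduced row count (test economy:
    rows are independent under per-row demodulation)."""
    return make_bowel_scene(shape=(128, 1280), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
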