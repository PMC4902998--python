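import numpy as np
import pytest

from filascan.io import GrayImage, PipelineConfig


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def gray():
    """Factory: wrap a float array in [0,1] as a GrayImage."""
    def make(arr, **kw):
        return GrayImage(np.asarray(arr, float), **kw)
    return make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
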