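import numpy as np
import pytest

from sscswallow.dsp import FeatureConfig
from sscswallow.synth import GeneratorConfig


@pytest.fixture(scope="session")
def feature_config() -> FeatureConfig:
    return FeatureConfig()


@pytest.fixture(scope="session")
def fast_gen_cfg() -> GeneratorConfig:
    """Short-duration generator config for quick unit tests."""
    return GeneratorConfig(duration_range_s=(0.2, 0.4), seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
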