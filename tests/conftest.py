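import numpy as np
import pytest

from sts_sonify.config import PipelineConfig
from sts_sonify.simulate import default_pattern_specs, generate_motion


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig.default()


@pytest.fixture(scope="session")
def specs():
    return default_pattern_specs(seed=0)


@pytest.fixture(scope="session")
def p1_motion(specs):
    return generate_motion(specs["P1"])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
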