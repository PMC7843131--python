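import numpy as np
import pytest

from rapmicro.optics import PRESETS


@pytest.fixture
def config1():
    """1x four-dish instrument: 25/100 mm lens, 640x480 sensor."""
    return PRESETS["config1"]


@pytest.fixture
def config2():
    """1.4x 96-well instrument: 6/72 mm lens, 1280x1024 sensor."""
    return PRESETS["config2"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
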