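import numpy as np
import pytest

from frailsense.config import DetectorConfig
from frailsense.streams import GRAVITY, AccelStream


@pytest.fixture
def config() -> DetectorConfig:
    return DetectorConfig()


@pytest.fixture
def standing_stream() -> AccelStream:
    """10 s of motionless standing (gravity on the trunk axis)."""
    a = np.zeros((400, 3))
    a[:, 0] = GRAVITY
    return AccelStream(a)


@pytest.fixture
def lying_stream() -> AccelStream:
    """10 s of motionless lying (gravity orthogonal to the trunk axis)."""
    a = np.zeros((400, 3))
    a[:, 2] = GRAVITY
    return AccelStream(a)
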