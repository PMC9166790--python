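import numpy as np
import pytest

from volamp.device_model import DeviceParams, DeviceState
from volamp.reservoir import Alphabet


@pytest.fixture
def params() -> DeviceParams:
    return DeviceParams()

@pytest.fixture
def fresh_state() -> DeviceState:
    return DeviceState()

@pytest.fixture
def abcd_alphabet() -> list[str]:
    return ["A", "B", "C", "D"]

@pytest.fixture
def kaist_alphabet() -> Alphabet:
    return Alphabet.from_corpus(["KAIST"])

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
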