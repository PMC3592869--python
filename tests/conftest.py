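import numpy as np
import pytest

from canmap.network import BooleanNode
from canmap.spn import build_spn, reference_catalog


def automaton_x_lut() -> np.ndarray:
    """The six-input worked example: transitions to on exactly when input 2
    is off, input 3 is on, and among the remaining four inputs at least one
    is on and at least one is off."""
    lut = np.zeros(64, dtype=np.uint8)
    for row in range(64):
        x = [(row >> (5 - j)) & 1 for j in range(6)]
        others = x[0] + x[3] + x[4] + x[5]
        lut[row] = int(x[1] == 0 and x[2] == 1 and 0 < others < 4)
    return lut


@pytest.fixture(scope="session")
def automaton_x() -> BooleanNode:
    return BooleanNode(0, "x", (1, 2, 3, 4, 5, 6), automaton_x_lut())


@pytest.fixture(scope="session")
def spn_cell():
    return build_spn("single_cell_merged_inputs")


@pytest.fixture(scope="session")
def spn_cell_explicit():
    return build_spn("single_cell_explicit")


@pytest.fixture(scope="session")
def spn_parasegment():
    return build_spn("parasegment_4cell")


@pytest.fixture(scope="session")
def catalog():
    return reference_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
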