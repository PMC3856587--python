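import numpy as np
import pytest
from hypothesis import settings

from serohpa import build_mdd_network, parse_bnet

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return build_mdd_network()


@pytest.fixture()
def not_copy_net():
    """2-node network A <- NOT B, B <- A (period-4 rotor)."""
    return parse_bnet("targets, factors\nA, !B\nB, A\n")


@pytest.fixture()
def identity_net():
    """3-node network where every node copies itself (all states fixed)."""
    return parse_bnet("targets, factors\nA, A | A\nB, B | B\nC, C | C\n")
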