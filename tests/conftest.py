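from itertools import product

import pytest

from boolscreen import BooleanNetwork, Var, parse_network

# The worked three-component example network used throughout:
#   f1 = !x1,  f2 = x1 | x2,  f3 = x1 & !x2
TOY3_TEXT = "x1, !x1\nx2, x1 | x2\nx3, x1 & !x2"


@pytest.fixture
def toy3() -> BooleanNetwork:
    return parse_network(TOY3_TEXT).network


def identity_network(n: int) -> BooleanNetwork:
    """f_i = x_i for all i: every state is a steady state."""
    return BooleanNetwork(
        tuple(f"x{i + 1}" for i in range(n)),
        tuple(Var(i) for i in range(n)),
    )


def all_states(n: int):
    return product((0, 1), repeat=n)


@pytest.fixture
def cascade6() -> BooleanNetwork:
    """Six-component damage -> inflammation cascade used for screen tests.

    dmg is an input; the signal runs dmg -> kin -> mod -> tf, tf has a
    self-sustaining loop gated by the inhibitor inh, and cytokine il reads
    tf.  With dmg fixed on, the sole attractor has il active; knocking
    down any member of the relay (or over-expressing inh) silences il.
    """
    text = """
    dmg, dmg
    kin, dmg & !inh
    mod, kin
    tf,  mod | (tf & !inh)
    inh, 0
    il,  tf
    """
    return parse_network(text).network
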