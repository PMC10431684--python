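import random

import pytest

from nsslink.network_io import BipartiteNetwork, FormalContext


@pytest.fixture
def toy_context():
    """Y = {(g0,m0), (g0,m1), (g1,m1), (g2,m2)} on a 3x3 grid."""
    return FormalContext(3, 3, frozenset({(0, 0), (0, 1), (1, 1), (2, 2)}))


@pytest.fixture
def identity_context():
    return FormalContext(3, 3, frozenset({(0, 0), (1, 1), (2, 2)}))


@pytest.fixture
def full_context():
    return FormalContext(2, 2, frozenset({(0, 0), (0, 1), (1, 0), (1, 1)}))


@pytest.fixture
def empty_context():
    return FormalContext(2, 2, frozenset())


@pytest.fixture
def two_block_context():
    """Blocks {g0..g3}x{m0..m3} and {g2..g5}x{m2..m5}, fully linked."""
    inc = set()
    for g in range(4):
        for m in range(4):
            inc.add((g, m))
    for g in range(2, 6):
        for m in range(2, 6):
            inc.add((g, m))
    return FormalContext(6, 6, frozenset(inc))


@pytest.fixture
def small_network():
    return BipartiteNetwork(
        ["u1", "u2"],
        ["m1", "m2", "m3"],
        {("u1", "m1"), ("u1", "m2"), ("u2", "m1"), ("u2", "m3")},
    )


def random_context(seed: int, max_side: int = 10, density: float | None = None):
    rng = random.Random(seed)
    n = rng.randint(1, max_side)
    m = rng.randint(1, max_side)
    d = density if density is not None else rng.choice([0.1, 0.3, 0.5, 0.9])
    inc = frozenset(
        (g, a) for g in range(n) for a in range(m) if rng.random() < d
    )
    return FormalContext(n, m, inc)
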