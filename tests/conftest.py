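import numpy as np
import pytest

from maxweb import FoodWeb, random_web_fixed_L


@pytest.fixture
def chain_web() -> FoodWeb:
    """Three-species chain: A eats B, B eats C."""
    adj = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=bool)
    return FoodWeb(["A", "B", "C"], adj)


@pytest.fixture
def fork_web() -> FoodWeb:
    """A eats B and C; B eats C (omnivore on top)."""
    adj = np.array([[0, 1, 1], [0, 0, 1], [0, 0, 0]], dtype=bool)
    return FoodWeb(["A", "B", "C"], adj)


def random_webs(n: int, s_lo: int = 3, s_hi: int = 8, seed: int = 0):
    """Seeded random webs with at least one off-diagonal link each."""
    rng = np.random.default_rng(seed)
    webs = []
    while len(webs) < n:
        S = int(rng.integers(s_lo, s_hi + 1))
        L = int(rng.integers(1, S * S + 1))
        w = random_web_fixed_L(S, L, rng)
        a = w.adjacency.copy()
        np.fill_diagonal(a, False)
        if a.any():
            webs.append(w)
    return webs
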