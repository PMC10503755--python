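"""Synthetic food webs, abundances and (S, L) datasets for testing and demos.

Stands in for empirical web collections: uniform random Boolean webs,
webs realizing a prescribed joint degree sequence, log-normal abundance
vectors for the neutral model, and (S, L) datasets drawn from the
flexible-links generative model with known (mu, phi).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core import FoodWeb, JointDegreeSequence
from .anneal import random_web_fixed_L, randomize_fixed_jds

__all__ = [
    "generate_random_webs",
    "web_from_joint_degree_sequence",
    "generate_abundances",
    "generate_SL_dataset",
]


def generate_random_webs(
    S: int, L: int, n: int, seed: int | None = None
) -> list[FoodWeb]:
    """n independent uniform webs with exactly L links among S^2 cells."""
    if not 0 <= L <= S * S:
        raise ValueError(f"L={L} infeasible for S={S}")
    rng = np.random.default_rng(seed)
    return [random_web_fixed_L(S, L, rng) for _ in range(n)]


def web_from_joint_degree_sequence(
    seq: JointDegreeSequence, seed: int | None = None, shuffle_swaps: int | None = None
) -> FoodWeb:
    """Construct a Boolean web with the exact prescribed margins.

    Row sums are k_out (prey counts) and column sums k_in (predator
    counts). Uses the greedy Gale-Ryser-style fill — each predator's prey
    are assigned to the columns with the largest remaining predator
    capacity — which succeeds whenever the sequence is realizable, then
    shuffles with seeded checkerboard swaps (default 10 L) so different
    seeds give different realizations. Uniformity over realizations is
    not claimed. Raises on infeasible sequences.
    """
    k_in = seq.k_in.copy()
    k_out = seq.k_out
    S = len(seq)
    if k_in.sum() != k_out.sum():
        raise ValueError("sum of k_in must equal sum of k_out")
    if (k_in > S).any() or (k_out > S).any():
        raise ValueError("degrees cannot exceed S")
    adj = np.zeros((S, S), dtype=bool)
    remaining = k_in.astype(float)
    # fill rows from most to least general predator
    for i in np.argsort(-k_out, kind="stable"):
        need = int(k_out[i])
        if need == 0:
            continue
        order = np.lexsort((np.arange(S), -remaining))
        chosen = order[:need]
        if remaining[chosen[-1]] <= 0:
            raise ValueError("joint degree sequence is not realizable")
        adj[i, chosen] = True
        remaining[chosen] -= 1
    if (remaining != 0).any():
        raise ValueError("joint degree sequence is not realizable")
    web = FoodWeb([f"s{i}" for i in range(S)], adj)
    L = int(k_out.sum())
    swaps = 10 * L if shuffle_swaps is None else shuffle_swaps
    if swaps and L:
        web = randomize_fixed_jds(web, swaps, seed)
    return web


def generate_abundances(
    S: int,
    lognormal_mu: float = 0.0,
    lognormal_sd: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Strictly positive log-normal abundances for S species."""
    rng = np.random.default_rng(seed)
    return rng.lognormal(lognormal_mu, lognormal_sd, size=S)


def generate_SL_dataset(
    m: int,
    mu: float = 0.3,
    phi: float = 3.0,
    S_range: tuple[int, int] = (10, 60),
    seed: int | None = None,
) -> list[tuple[int, int]]:
    """(S, L) pairs from the flexible-links generative model.

    S is uniform on the inclusive range; L = (S - 1) + BetaBinomial(
    S^2 - (S - 1), mu e^phi, (1 - mu) e^phi), so every L lies in
    [S - 1, S^2].
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < mu < 1:
        raise ValueError("mu must be in (0, 1)")
    rng = np.random.default_rng(seed)
    a = mu * np.exp(phi)
    b = (1.0 - mu) * np.exp(phi)
    S = rng.integers(S_range[0], S_range[1] + 1, size=m)
    trials = S * S - (S - 1)
    L_fl = stats.betabinom.rvs(trials, a, b, random_state=rng)
    return [(int(s), int(s - 1 + l)) for s, l in zip(S, np.atleast_1d(L_fl))]
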