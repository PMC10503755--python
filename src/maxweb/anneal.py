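"""Heuristic MaxEnt: simulated annealing toward maximum SVD entropy.

Finds the network configuration of (near-)maximum standardized SVD entropy
under one of two hard constraints:

* type I  — connectance: S and L fixed; proposals move one interaction to
  an empty cell.
* type II — joint degree sequence: all row and column sums fixed;
  proposals are checkerboard double-swaps, which preserve every margin
  exactly. The diagonal participates like any other cell, so cannibal
  links may appear or disappear as long as margins hold.

Each chain starts from an independent randomization of the constraint set
and runs a geometric cooling schedule: uphill moves in entropy are always
accepted, downhill moves with probability exp(dJ / T_t). The best
configuration across chains is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FoodWeb
from .svdent import svd_entropy

__all__ = [
    "AnnealSchedule",
    "AnnealResult",
    "random_web_fixed_L",
    "randomize_fixed_jds",
    "propose_type1",
    "propose_type2",
    "metropolis_accept",
    "anneal",
]

#: attempts to find a valid checkerboard swap before giving up on a proposal
SWAP_RETRY_CAP = 100


@dataclass
class AnnealSchedule:
    """Annealing parameters; defaults follow the 4-chain, 2000-step, T0=0.2 setup."""

    chains: int = 4
    steps: int = 2000
    t0: float = 0.2
    cooling_factor: float | None = None  # default: reach 1e-6 * t0 at the last step
    proposals_per_step: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.cooling_factor is None:
            self.cooling_factor = float(1e-6 ** (1.0 / self.steps))
        if not 0 < self.cooling_factor < 1:
            raise ValueError("cooling_factor must be in (0, 1)")


@dataclass
class AnnealResult:
    best_web: FoodWeb
    best_entropy: float
    traces: np.ndarray  # (chains, steps) best-so-far standardized SVD entropy
    constraint_type: str  # "I" or "II"


def metropolis_accept(dJ: float, T: float, rng: np.random.Generator) -> bool:
    """Accept uphill moves always; downhill with probability exp(dJ / T)."""
    if dJ >= 0:
        return True
    if T <= 0:
        return False
    return rng.random() < np.exp(dJ / T)


def random_web_fixed_L(
    S: int, L: int, seed: int | np.random.Generator | None = None
) -> FoodWeb:
    """Uniformly random Boolean web: L ones among the S^2 cells (diagonal included)."""
    if not 0 <= L <= S * S:
        raise ValueError(f"L={L} out of range for S={S}")
    rng = np.random.default_rng(seed)
    cells = rng.choice(S * S, size=L, replace=False)
    adj = np.zeros(S * S, dtype=bool)
    adj[cells] = True
    return FoodWeb([f"s{i}" for i in range(S)], adj.reshape(S, S))


def _find_checkerboard(adj: np.ndarray, rng: np.random.Generator):
    """One valid checkerboard swap (i,j,k,l) or None after SWAP_RETRY_CAP tries.

    Picks two random 1-cells (i,j), (k,l); the swap to (i,l), (k,j) is
    valid when those two cells are 0 (which forces i != k and j != l).
    """
    ones = np.flatnonzero(adj)
    if ones.size < 2:
        return None
    n = adj.shape[0]
    for _ in range(SWAP_RETRY_CAP):
        a, b = rng.choice(ones.size, size=2, replace=False)
        i, j = divmod(int(ones[a]), n)
        k, l = divmod(int(ones[b]), n)
        if not adj[i, l] and not adj[k, j]:
            return i, j, k, l
    return None


def randomize_fixed_jds(
    web: FoodWeb, n_swaps: int, seed: int | np.random.Generator | None = None
) -> FoodWeb:
    """Shuffle a web by accepted checkerboard swaps; margins are invariant.

    Webs admitting no valid swap are returned unchanged.
    """
    rng = np.random.default_rng(seed)
    adj = web.adjacency.copy()
    done = 0
    while done < n_swaps:
        found = _find_checkerboard(adj, rng)
        if found is None:
            break
        i, j, k, l = found
        adj[i, j] = adj[k, l] = False
        adj[i, l] = adj[k, j] = True
        done += 1
    return FoodWeb(list(web.species), adj)


def propose_type1(
    web: FoodWeb, rng: np.random.Generator
) -> tuple[FoodWeb, bool]:
    """Move one uniformly chosen interaction to a uniformly chosen empty cell.

    Preserves L; returns (candidate, changed). A full or empty web admits
    no move and is returned unchanged.
    """
    flat = web.adjacency.ravel()
    ones = np.flatnonzero(flat)
    zeros = np.flatnonzero(~flat)
    if ones.size == 0 or zeros.size == 0:
        return web, False
    src = int(ones[rng.integers(ones.size)])
    dst = int(zeros[rng.integers(zeros.size)])
    adj = web.adjacency.copy()
    adj.flat[src] = False
    adj.flat[dst] = True
    return FoodWeb(list(web.species), adj), True


def propose_type2(
    web: FoodWeb, rng: np.random.Generator
) -> tuple[FoodWeb, bool]:
    """One checkerboard double-swap; preserves the full joint degree sequence.

    Returns (candidate, changed); unchanged if no valid swap is found
    within the retry cap.
    """
    found = _find_checkerboard(web.adjacency, rng)
    if found is None:
        return web, False
    i, j, k, l = found
    adj = web.adjacency.copy()
    adj[i, j] = adj[k, l] = False
    adj[i, l] = adj[k, j] = True
    return FoodWeb(list(web.species), adj), True


def anneal(
    web: FoodWeb,
    constraint: str,
    schedule: AnnealSchedule | None = None,
    debug_checks: bool = False,
) -> AnnealResult:
    """Search for the maximum-SVD-entropy configuration under a constraint.

    ``constraint`` is ``"I"`` (fix S and L) or ``"II"`` (fix the joint
    degree sequence of ``web``). Each chain is initialized independently
    (type I: uniform random web with the same L; type II: the input web
    shuffled by 10 L accepted swaps), then annealed with geometric
    cooling. With ``debug_checks`` the constraint is asserted at every
    step. Deterministic given ``schedule.seed``.
    """
    if web.L == 0:
        raise ValueError("cannot anneal an empty web")
    constraint = str(constraint).upper().lstrip("TYPE").strip() or constraint
    if constraint in ("1", "I"):
        constraint = "I"
    elif constraint in ("2", "II"):
        constraint = "II"
    else:
        raise ValueError(f"constraint must be 'I' or 'II', got {constraint!r}")
    sched = schedule or AnnealSchedule()
    S, L = web.S, web.L
    ref_rows = web.k_out.copy()
    ref_cols = web.k_in.copy()
    propose = propose_type1 if constraint == "I" else propose_type2

    master = np.random.default_rng(sched.seed)
    chain_rngs = master.spawn(sched.chains)

    best_web: FoodWeb | None = None
    best_J = -np.inf
    traces = np.empty((sched.chains, sched.steps))

    for c, rng in enumerate(chain_rngs):
        if constraint == "I":
            current = random_web_fixed_L(S, L, rng)
        else:
            current = randomize_fixed_jds(web, 10 * L, rng)
        J = svd_entropy(current.adjacency)
        chain_best_web, chain_best_J = current, J
        T = sched.t0
        for t in range(sched.steps):
            for _ in range(sched.proposals_per_step):
                cand, changed = propose(current, rng)
                if changed:
                    Jc = svd_entropy(cand.adjacency)
                    if metropolis_accept(Jc - J, T, rng):
                        current, J = cand, Jc
                if debug_checks:
                    if constraint == "I":
                        assert current.L == L
                    else:
                        assert np.array_equal(current.k_out, ref_rows)
                        assert np.array_equal(current.k_in, ref_cols)
            if J > chain_best_J:
                chain_best_web, chain_best_J = current, J
            traces[c, t] = chain_best_J
            T *= sched.cooling_factor
        if chain_best_J > best_J:
            best_web, best_J = chain_best_web, chain_best_J

    assert best_web is not None
    return AnnealResult(
        best_web=best_web,
        best_entropy=float(best_J),
        traces=traces,
        constraint_type=constraint,
    )
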