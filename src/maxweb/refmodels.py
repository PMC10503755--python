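"""Topological null models and the abundance-based neutral model.

All three models turn an observed web (or abundance vector) into an S x S
matrix of interaction probabilities:

* type I null — every cell gets the connectance, p = L / S^2;
* type II null — p(i -> j) = (k_in(j)/S + k_out(i)/S) / 2, blending the
  degree sequences of predator and prey;
* neutral — p(i -> j) proportional to the product of relative abundances
  (n_i / N)(n_j / N), scaled so the expected link count matches a target.

Probabilistic webs are realized as Boolean webs by repeated Bernoulli
sampling: the L cells sampled most often across draws become the links,
so realized webs match the empirical interaction count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FoodWeb

__all__ = [
    "ProbabilisticWeb",
    "null_type1",
    "null_type2",
    "neutral_model",
    "realize_boolean",
]


@dataclass
class ProbabilisticWeb:
    """S x S interaction probabilities plus the model that produced them."""

    p: np.ndarray
    provenance: str  # "null1" | "null2" | "neutral"
    species: list[str] | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("probability matrix must be square")
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def S(self) -> int:
        return self.p.shape[0]


def null_type1(web: FoodWeb) -> ProbabilisticWeb:
    """Connectance-based null: every cell equals L / S^2."""
    c = web.L / web.S**2
    return ProbabilisticWeb(
        np.full((web.S, web.S), c), "null1", list(web.species)
    )


def null_type2(web: FoodWeb) -> ProbabilisticWeb:
    """Degree-based null: p(i,j) = (k_in(j)/S + k_out(i)/S) / 2.

    The cell average equals the connectance because both degree sequences
    sum to L.
    """
    S = web.S
    p = 0.5 * (web.k_in[None, :] / S + web.k_out[:, None] / S)
    return ProbabilisticWeb(p, "null2", list(web.species))


def neutral_model(
    abundances: np.ndarray,
    target_L: int | None = None,
    species: list[str] | None = None,
) -> ProbabilisticWeb:
    """Neutral probabilities from relative abundances.

    Raw weights are (n_i/N)(n_j/N). With ``target_L`` given, weights are
    scaled so probabilities sum to target_L, iteratively capping cells at
    1 and rescaling the remainder (needed when dominant species would
    otherwise exceed probability 1). With ``target_L=None`` the raw
    proportional weights are returned unscaled.
    """
    n = np.asarray(abundances, dtype=float)
    if (n <= 0).any():
        raise ValueError("abundances must all be positive")
    rel = n / n.sum()
    q = np.outer(rel, rel)
    if target_L is None:
        return ProbabilisticWeb(q, "neutral", species)
    if not 0 <= target_L <= n.size**2:
        raise ValueError(f"target_L={target_L} out of range for S={n.size}")
    p = np.zeros_like(q)
    capped = np.zeros(q.shape, dtype=bool)
    for _ in range(q.size + 1):
        free_mass = q[~capped].sum()
        remaining = target_L - capped.sum()
        if remaining < 0:
            raise ValueError("target_L below the number of saturated cells")
        scale = 0.0 if free_mass == 0 else remaining / free_mass
        p = np.where(capped, 1.0, q * scale)
        newly = (p > 1.0) & ~capped
        if not newly.any():
            break
        capped |= newly
    return ProbabilisticWeb(np.clip(p, 0.0, 1.0), "neutral", species)


def realize_boolean(
    pweb: ProbabilisticWeb,
    L: int,
    n_draws: int = 100,
    seed: int | np.random.Generator | None = None,
) -> FoodWeb:
    """Boolean realization with exactly L links.

    Draws ``n_draws`` independent Bernoulli matrices from the probability
    web, counts per-cell successes, and keeps the L most-sampled cells.
    Ties at the cut are broken uniformly at random (seeded).
    """
    S = pweb.S
    if not 0 <= L <= S * S:
        raise ValueError(f"L={L} out of range for S={S}")
    rng = np.random.default_rng(seed)
    counts = (rng.random((n_draws, S, S)) < pweb.p).sum(axis=0).ravel()
    tiebreak = rng.random(counts.size)
    order = np.lexsort((tiebreak, -counts))
    adj = np.zeros(S * S, dtype=bool)
    adj[order[:L]] = True
    species = pweb.species or [f"s{i}" for i in range(S)]
    return FoodWeb(list(species), adj.reshape(S, S))
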