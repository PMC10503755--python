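"""Analytic maximum-entropy degree distributions for food webs.

Given only the species count S and interaction count L, the least-biased
joint distribution of a species' number of predators (k_in) and prey
(k_out) maximizes Shannon entropy subject to normalization and to both
marginal means equalling the linkage density L/S. The solution is
exponential-family,

    p(k_in, k_out) = exp(-lam2*k_in - lam3*k_out) / Z,

on the lattice [0, S]^2, with Z the partition function. Because both mean
constraints carry the same target, the multipliers coincide (lam2 = lam3)
and the distribution is symmetric in its arguments; the problem reduces to
a one-dimensional root find in lambda.

The degree distribution p(k) of the total degree k = k_in + k_out is either
obtained by marginalizing the joint solution, or solved directly as a
geometric-form MaxEnt distribution with mean 2L/S. The two routes agree
only when the direct solve uses the same support and lattice multiplicity
as the marginal (see ``lattice_degeneracy``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import JointDegreeSequence

__all__ = [
    "JointDegreeDistribution",
    "DegreeDistribution",
    "solve_joint_degree_distribution",
    "marginalize_to_degree_distribution",
    "solve_degree_distribution",
    "isolated_species_probability",
    "sample_joint_degree_sequence",
    "align_sequences_by_rank",
]


class InfeasibleConstraintError(ValueError):
    """The mean constraint cannot be met by any distribution on the support."""


@dataclass
class JointDegreeDistribution:
    """MaxEnt joint distribution of (k_in, k_out) on [0, S]^2."""

    S: int
    L: float
    lambda2: float
    lambda3: float
    Z: float
    p: np.ndarray  # (S+1, S+1); p[k_in, k_out]

    @property
    def mean_k_in(self) -> float:
        k = np.arange(self.S + 1)
        return float((self.p.sum(axis=1) * k).sum())

    @property
    def mean_k_out(self) -> float:
        k = np.arange(self.S + 1)
        return float((self.p.sum(axis=0) * k).sum())

    def entropy(self) -> float:
        """Shannon entropy -sum p ln p (nats), ignoring zero cells."""
        p = self.p[self.p > 0]
        return float(-(p * np.log(p)).sum())


@dataclass
class DegreeDistribution:
    """MaxEnt distribution of the total degree k = k_in + k_out."""

    S: int
    L: float
    lambda2: float
    Z: float
    p: np.ndarray  # over k = 0 .. k_max

    @property
    def k_max(self) -> int:
        return len(self.p) - 1

    @property
    def mean(self) -> float:
        return float((np.arange(len(self.p)) * self.p).sum())


def _weighted_geometric(lam: float, k_max: int, weights: np.ndarray | None):
    """Normalized p(k) ~ w(k) exp(-lam k) on 0..k_max; returns (p, Z-like)."""
    k = np.arange(k_max + 1, dtype=float)
    logw = np.zeros_like(k) if weights is None else np.log(weights)
    logits = logw - lam * k
    shift = logits.max()
    unnorm = np.exp(logits - shift)
    p = unnorm / unnorm.sum()
    # Z on the original (unshifted) scale; may overflow only for extreme lam
    Z = float(np.exp(shift) * unnorm.sum())
    return p, Z


def _solve_lambda(
    target_mean: float, k_max: int, weights: np.ndarray | None = None, tol: float = 1e-12
) -> float:
    """Root of mean(lambda) = target for p(k) ~ w(k) e^{-lam k} on [0, k_max].

    The mean is strictly decreasing in lambda, from k_max (lam -> -inf)
    to 0 (lam -> +inf), so the root is unique on the open interval.
    """
    if not 0.0 < target_mean < k_max:
        raise InfeasibleConstraintError(
            f"mean constraint {target_mean} not attainable on [0, {k_max}]"
        )

    def resid(lam: float) -> float:
        p, _ = _weighted_geometric(lam, k_max, weights)
        return float((np.arange(k_max + 1) * p).sum()) - target_mean

    if abs(resid(0.0)) <= tol:
        return 0.0
    a, b = -1.0, 1.0
    while resid(a) < 0:  # mean too small -> need more negative lambda
        a *= 2.0
        if a < -1e6:
            raise RuntimeError("failed to bracket lambda (lower)")
    while resid(b) > 0:
        b *= 2.0
        if b > 1e6:
            raise RuntimeError("failed to bracket lambda (upper)")
    return float(brentq(resid, a, b, xtol=tol, rtol=8.9e-16))


def solve_joint_degree_distribution(
    S: int, L: float, tol: float = 1e-12
) -> JointDegreeDistribution:
    """MaxEnt joint degree distribution for a web with S species, L links.

    Reduces the two mean constraints (both L/S) to a single root find for
    lambda = lambda2 = lambda3; feasibility requires 0 < L < S^2 so that
    the marginal mean L/S lies strictly inside (0, S).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if not 0 < L < S * S:
        raise InfeasibleConstraintError(
            f"L={L} infeasible for S={S}: need 0 < L < S^2 so that L/S in (0, S)"
        )
    lam = _solve_lambda(L / S, S, tol=tol)
    k = np.arange(S + 1, dtype=float)
    logits = -lam * k[:, None] - lam * k[None, :]
    shift = logits.max()
    unnorm = np.exp(logits - shift)
    p = unnorm / unnorm.sum()
    Z = float(np.exp(shift) * unnorm.sum())
    jdd = JointDegreeDistribution(S=S, L=L, lambda2=lam, lambda3=lam, Z=Z, p=p)
    for mean in (jdd.mean_k_in, jdd.mean_k_out):
        if abs(mean - L / S) > max(1e-8, 100 * tol):
            raise RuntimeError(
                f"solver did not converge: marginal mean {mean} vs target {L / S}"
            )
    return jdd


def marginalize_to_degree_distribution(
    jdd: JointDegreeDistribution, k_max: int | None = None
) -> DegreeDistribution:
    """Distribution of k = k_in + k_out from the joint table (anti-diagonal sums)."""
    if k_max is None:
        k_max = 2 * jdd.S
    p = np.zeros(k_max + 1)
    for k in range(k_max + 1):
        i = np.arange(max(0, k - jdd.S), min(k, jdd.S) + 1)
        p[k] = jdd.p[k - i, i].sum()
    return DegreeDistribution(S=jdd.S, L=jdd.L, lambda2=jdd.lambda2, Z=jdd.Z, p=p)


def lattice_multiplicity(S: int) -> np.ndarray:
    """Number of (k_in, k_out) pairs on [0,S]^2 with a given sum k in [0, 2S]."""
    k = np.arange(2 * S + 1)
    return (S + 1 - np.abs(k - S)).astype(float)


def solve_degree_distribution(
    S: int,
    L: float,
    k_support_max: int | None = None,
    tol: float = 1e-12,
    lattice_degeneracy: bool = False,
) -> DegreeDistribution:
    """Directly solve the MaxEnt total-degree distribution with mean 2L/S.

    With ``lattice_degeneracy=False`` (default) the solution is the pure
    geometric form p(k) = e^{-lambda k}/Z on [0, k_support_max] (default
    support up to S). With ``lattice_degeneracy=True`` the prior measure
    counts the (k_in, k_out) lattice pairs summing to k, the support is
    forced to [0, 2S], and the result coincides exactly with marginalizing
    the joint distribution — the sense in which both routes give the same
    answer on matched supports.
    """
    if lattice_degeneracy:
        k_support_max = 2 * S
        weights = lattice_multiplicity(S)
    else:
        k_support_max = S if k_support_max is None else k_support_max
        weights = None
    mean = 2 * L / S
    if not 0 < mean < k_support_max:
        raise InfeasibleConstraintError(
            f"mean degree {mean} not attainable on [0, {k_support_max}]"
        )
    lam = _solve_lambda(mean, k_support_max, weights=weights, tol=tol)
    p, Z = _weighted_geometric(lam, k_support_max, weights)
    return DegreeDistribution(S=S, L=L, lambda2=lam, Z=Z, p=p)


def isolated_species_probability(dd: DegreeDistribution) -> float:
    """Probability that a species has no interactions at all, p(k = 0)."""
    return float(dd.p[0])


def sample_joint_degree_sequence(
    jdd: JointDegreeDistribution,
    seed: int | np.random.Generator | None = None,
    max_repairs: int = 10**6,
) -> JointDegreeSequence:
    """One realization of the joint degree sequence with both totals fixed to L.

    S pairs are drawn iid from the joint distribution, then repaired:
    a uniformly chosen species' pair is resampled from the distribution
    conditioned on strictly reducing the total constraint discrepancy
    |sum k_in - L| + |sum k_out - L|, until both sums equal L exactly.
    The repair preserves the marginal shape approximately; each accepted
    repair reduces the discrepancy by at least one, so termination is
    guaranteed for feasible (integer) L.
    """
    rng = np.random.default_rng(seed)
    S = jdd.S
    L = int(round(jdd.L))
    flat = jdd.p.ravel()
    idx = rng.choice(flat.size, size=S, p=flat)
    k_in, k_out = np.divmod(idx, S + 1)
    k = np.arange(S + 1)

    repairs = 0
    while True:
        d_in = int(k_in.sum()) - L
        d_out = int(k_out.sum()) - L
        D = abs(d_in) + abs(d_out)
        if D == 0:
            break
        if repairs >= max_repairs:
            raise RuntimeError("fixed-total repair exceeded iteration cap")
        j = rng.integers(S)
        # discrepancy after giving species j the pair (a, b)
        new_in = np.abs(d_in - k_in[j] + k[:, None])
        new_out = np.abs(d_out - k_out[j] + k[None, :])
        improves = (new_in + new_out) < D
        repairs += 1
        if not improves.any():
            continue
        cond = np.where(improves, jdd.p, 0.0).ravel()
        pick = rng.choice(cond.size, p=cond / cond.sum())
        k_in[j], k_out[j] = divmod(pick, S + 1)
    return JointDegreeSequence(k_in, k_out)


def _rank_order(seq: JointDegreeSequence, key: str) -> np.ndarray:
    """Indices sorting a sequence descending by key, with deterministic ties."""
    kin, kout = seq.k_in, seq.k_out
    if key == "total":
        primary, secondary = kin + kout, kin
        tertiary = kout
    elif key == "in":
        primary, secondary, tertiary = kin, kout, np.zeros_like(kin)
    elif key == "out":
        primary, secondary, tertiary = kout, kin, np.zeros_like(kin)
    else:
        raise ValueError(f"key must be 'total', 'in' or 'out', got {key!r}")
    idx = np.arange(len(kin))
    # lexsort: last key is primary; negate for descending, index ascending
    return np.lexsort((idx, -tertiary, -secondary, -primary))


def align_sequences_by_rank(
    predicted: JointDegreeSequence,
    empirical: JointDegreeSequence,
    key: str = "total",
) -> list[tuple[int, int]]:
    """Pair species by rank and return per-rank (delta k_in, delta k_out).

    Both sequences are sorted descending by ``key`` ('total', 'in' or
    'out'; ties broken by the complementary degree then by index) and
    paired rank-for-rank; differences are predicted minus empirical.
    """
    if len(predicted) != len(empirical):
        raise ValueError(
            f"sequence lengths differ: {len(predicted)} vs {len(empirical)}"
        )
    po = _rank_order(predicted, key)
    eo = _rank_order(empirical, key)
    d_in = predicted.k_in[po] - empirical.k_in[eo]
    d_out = predicted.k_out[po] - empirical.k_out[eo]
    return [(int(a), int(b)) for a, b in zip(d_in, d_out)]
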