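"""Food-web structure measures used to evaluate MaxEnt and null models.

Covers nestedness (spectral radius), prey-averaged trophic levels and
derived quantities (maximum trophic level, omnivory), directed diameter,
trophic similarity, cannibalism, the 13-class three-species motif
profile, the KL divergence between in- and out-degree sequences, and the
standardized mean difference used to compare model predictions with
empirical measures across webs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .core import FoodWeb, JointDegreeSequence
from .svdent import svd_entropy

__all__ = [
    "MotifProfile",
    "MeasurePanel",
    "motif_catalog",
    "motif_profile",
    "nestedness_rho",
    "trophic_levels",
    "max_trophic_level",
    "diameter",
    "cannibalism",
    "omnivory",
    "max_similarity",
    "measure_panel",
    "kl_divergence_in_out",
    "standardized_mean_difference",
]

# off-diagonal cell order used to encode a 3-node digraph as 6 bits
_EDGE_SLOTS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
_PERMS = list(itertools.permutations(range(3)))


def _code(m: np.ndarray) -> int:
    bits = 0
    for b, (i, j) in enumerate(_EDGE_SLOTS):
        if m[i, j]:
            bits |= 1 << b
    return bits


def _from_code(code: int) -> np.ndarray:
    m = np.zeros((3, 3), dtype=bool)
    for b, (i, j) in enumerate(_EDGE_SLOTS):
        if code & (1 << b):
            m[i, j] = True
    return m


def _permute(m: np.ndarray, perm: tuple[int, ...]) -> np.ndarray:
    p = np.asarray(perm)
    return m[np.ix_(p, p)]


def _canon(m: np.ndarray) -> int:
    return min(_code(_permute(m, p)) for p in _PERMS)


def _weakly_connected(m: np.ndarray) -> bool:
    u = m | m.T
    reach = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in range(3):
            if u[i, j] and j not in reach:
                reach.add(j)
                frontier.append(j)
    return len(reach) == 3


# the five single-link motifs, labeled per the food-web motif tradition
# (species 0 = top): S1 tri-trophic chain, S2 omnivory, S3 feeding loop,
# S4 apparent competition (one predator, two prey), S5 exploitative
# competition (two predators, one prey)
_SINGLE_LINK_EDGES = {
    "S1": [(0, 1), (1, 2)],
    "S2": [(0, 1), (0, 2), (1, 2)],
    "S3": [(0, 1), (1, 2), (2, 0)],
    "S4": [(0, 1), (0, 2)],
    "S5": [(0, 2), (1, 2)],
}

_CATALOG: list[tuple[str, np.ndarray]] | None = None
_CANON_TO_LABEL: dict[int, str] | None = None


def _build_catalog() -> None:
    global _CATALOG, _CANON_TO_LABEL
    classes: dict[int, np.ndarray] = {}
    for code in range(64):
        m = _from_code(code)
        if not _weakly_connected(m):
            continue
        classes.setdefault(_canon(m), m)

    labels: dict[int, str] = {}
    for label, edges in _SINGLE_LINK_EDGES.items():
        m = np.zeros((3, 3), dtype=bool)
        for i, j in edges:
            m[i, j] = True
        labels[_canon(m)] = label
    doubles = sorted(
        (c for c in classes if c not in labels),
        key=lambda c: (int(classes[c].sum()), c),
    )
    for rank, c in enumerate(doubles, start=1):
        labels[c] = f"D{rank}"

    order = [f"S{i}" for i in range(1, 6)] + [f"D{i}" for i in range(1, 9)]
    by_label = {labels[c]: classes[c] for c in classes}
    _CATALOG = [(lab, by_label[lab]) for lab in order]
    _CANON_TO_LABEL = labels


def motif_catalog() -> list[tuple[str, np.ndarray]]:
    """The 13 connected three-species motifs as (label, 3x3 adjacency) pairs.

    Built by exhaustive enumeration of the 64 labeled 3-node digraphs
    (no self-loops), keeping weakly connected ones and grouping by
    isomorphism. Labels S1-S5 are the single-link motifs; D1-D8 contain
    at least one bidirectional pair (ordered by link count, then by
    canonical code, for stability).
    """
    if _CATALOG is None:
        _build_catalog()
    assert _CATALOG is not None
    return [(lab, m.copy()) for lab, m in _CATALOG]


@dataclass
class MotifProfile:
    counts: dict[str, int]
    proportions: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def motif_profile(web: FoodWeb) -> MotifProfile:
    """Census of connected triads by motif class.

    Every 3-species subset whose induced subgraph — self-loops stripped —
    is weakly connected contributes one count to its isomorphism class;
    proportions normalize over all counted triads. Webs with S < 3 (or
    no connected triad) return zero counts and zero proportions.
    """
    if _CANON_TO_LABEL is None:
        _build_catalog()
    assert _CANON_TO_LABEL is not None
    labels = [lab for lab, _ in motif_catalog()]
    counts = {lab: 0 for lab in labels}
    adj = web.adjacency
    for tri in itertools.combinations(range(web.S), 3):
        sub = adj[np.ix_(tri, tri)].copy()
        np.fill_diagonal(sub, False)
        if not _weakly_connected(sub):
            continue
        counts[_CANON_TO_LABEL[_canon(sub)]] += 1
    total = sum(counts.values())
    props = {
        lab: (c / total if total else 0.0) for lab, c in counts.items()
    }
    return MotifProfile(counts=counts, proportions=props)


def nestedness_rho(web: FoodWeb, normalized: bool = True) -> float:
    """Spectral radius of the adjacency matrix; normalized by sqrt(L).

    The spectral radius grows with how nested the diets are; dividing by
    its sqrt(L) scale makes webs of different sizes comparable.
    """
    if web.L == 0:
        raise ValueError("nestedness undefined for an empty web")
    eig = np.linalg.eigvals(web.adjacency.astype(float))
    rho = float(np.abs(eig).max())
    return rho / np.sqrt(web.L) if normalized else rho


def _prey_matrix(web: FoodWeb) -> np.ndarray:
    """Row-normalized predator->prey matrix, self-loops removed; basal rows zero."""
    a = web.adjacency.astype(float).copy()
    np.fill_diagonal(a, 0.0)
    nprey = a.sum(axis=1)
    m = np.zeros_like(a)
    feeders = nprey > 0
    m[feeders] = a[feeders] / nprey[feeders, None]
    return m


def trophic_levels(web: FoodWeb, tol: float = 1e-8, max_iter: int = 10**4) -> np.ndarray:
    """Prey-averaged trophic levels: TL(i) = 1 + mean TL over i's prey.

    Self-loops are removed first, so a pure cannibal is basal (TL = 1).
    Solved as the linear system (I - M) TL = 1; if that fails (closed
    feeding cycles make the system singular), a damped fixed-point
    iteration is tried, and a cycle that admits no finite prey-averaged
    level raises an error naming the component.
    """
    m = _prey_matrix(web)
    S = web.S
    ones = np.ones(S)
    try:
        tl = np.linalg.solve(np.eye(S) - m, ones)
        if np.isfinite(tl).all() and np.abs((np.eye(S) - m) @ tl - ones).max() < 1e-6:
            return tl
    except np.linalg.LinAlgError:
        pass
    # damped fixed point for the near-singular case
    tl = np.ones(S)
    for _ in range(max_iter):
        new = 0.5 * tl + 0.5 * (1.0 + m @ tl)
        if np.abs(new - tl).max() < tol:
            return new
        tl = new
    g = nx.from_numpy_array(m > 0, create_using=nx.DiGraph)
    cyclic = [
        sorted(web.species[i] for i in comp)
        for comp in nx.strongly_connected_components(g)
        if len(comp) > 1
    ]
    raise RuntimeError(
        f"trophic levels did not converge; cyclic component(s) with no basal "
        f"energy pathway: {cyclic}"
    )


def max_trophic_level(web: FoodWeb) -> float:
    """Longest energy pathway, as the maximum prey-averaged trophic level."""
    return float(trophic_levels(web).max())


def diameter(web: FoodWeb) -> int:
    """Longest finite shortest directed path over ordered reachable pairs."""
    a = web.adjacency.copy()
    np.fill_diagonal(a, False)
    if not a.any():
        raise ValueError("diameter undefined for a web with no edges")
    g = nx.from_numpy_array(a, create_using=nx.DiGraph)
    best = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for target, d in lengths.items():
            if d > best:
                best = d
    return best


def cannibalism(web: FoodWeb) -> float:
    """Proportion of species that prey on themselves (diagonal 1s / S)."""
    return float(np.diagonal(web.adjacency).sum()) / web.S


def omnivory(web: FoodWeb, tol: float = 1e-6) -> float:
    """Proportion of species feeding on prey at unequal trophic levels.

    A species counts as omnivorous when it has at least two prey (self
    excluded) whose trophic levels are not all equal within ``tol``.
    """
    tl = trophic_levels(web)
    a = web.adjacency.copy()
    np.fill_diagonal(a, False)
    count = 0
    for i in range(web.S):
        prey = np.flatnonzero(a[i])
        if prey.size >= 2 and tl[prey].max() - tl[prey].min() > tol:
            count += 1
    return count / web.S


def _similarity(a: np.ndarray, i: int, j: int) -> float:
    """Trophic similarity: shared prey plus shared predators over the unions."""
    shared = (a[i] & a[j]).sum() + (a[:, i] & a[:, j]).sum()
    union = (a[i] | a[j]).sum() + (a[:, i] | a[:, j]).sum()
    return shared / union if union else 0.0


def max_similarity(web: FoodWeb) -> float:
    """MxSim: mean over species of the maximum trophic similarity to any other."""
    if web.S < 2:
        return 0.0
    a = web.adjacency.copy()
    np.fill_diagonal(a, False)
    vals = [
        max(_similarity(a, i, j) for j in range(web.S) if j != i)
        for i in range(web.S)
    ]
    return float(np.mean(vals))


@dataclass
class MeasurePanel:
    """The standard evaluation panel of whole-web structure measures."""

    rho: float
    maxtl: float
    diam: int
    mxsim: float
    cannib: float
    omniv: float
    entropy: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def measure_panel(web: FoodWeb) -> MeasurePanel:
    """Compute the full panel on one web (needs at least one non-loop edge)."""
    return MeasurePanel(
        rho=nestedness_rho(web),
        maxtl=max_trophic_level(web),
        diam=diameter(web),
        mxsim=max_similarity(web),
        cannib=cannibalism(web),
        omniv=omnivory(web),
        entropy=svd_entropy(web.adjacency),
    )


def kl_divergence_in_out(
    seq: JointDegreeSequence,
    direction: str = "in_vs_out",
    epsilon: float = 1e-10,
) -> float:
    """KL divergence between the in- and out-degree frequency distributions.

    Degree frequencies are tabulated over 0..S, smoothed by ``epsilon``
    per bin and renormalized (so disjoint supports stay finite).
    ``direction`` picks P || Q: ``in_vs_out`` or ``out_vs_in``.
    """
    if len(seq) == 0:
        raise ValueError("empty degree sequence")
    S = len(seq)
    bins = np.arange(S + 2)
    f_in = np.histogram(seq.k_in, bins=bins)[0] / S
    f_out = np.histogram(seq.k_out, bins=bins)[0] / S
    if direction == "in_vs_out":
        P, Q = f_in, f_out
    elif direction == "out_vs_in":
        P, Q = f_out, f_in
    else:
        raise ValueError(f"direction must be 'in_vs_out' or 'out_vs_in', got {direction!r}")
    P = (P + epsilon) / (P + epsilon).sum()
    Q = (Q + epsilon) / (Q + epsilon).sum()
    return float((P * np.log(P / Q)).sum())


def standardized_mean_difference(
    predicted: np.ndarray, empirical: np.ndarray
) -> float:
    """mean(predicted - empirical) / sd(empirical) over paired webs.

    Positive values mean the measure is overestimated on average.
    """
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(empirical, dtype=float)
    if p.shape != e.shape or p.ndim != 1:
        raise ValueError("inputs must be paired 1-D arrays of equal length")
    sd = e.std(ddof=1)
    if not sd > 0:
        raise ValueError("empirical values have zero variance")
    return float((p - e).mean() / sd)
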