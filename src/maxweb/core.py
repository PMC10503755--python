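"""Core food-web data structures and tabular I/O.

A food web is a directed Boolean graph on S species: ``a[i, j] = 1`` means
species *i* preys on species *j* (rows are predators, columns are prey).
Self-loops on the diagonal represent cannibalism. The out-degree of a
species is its generality (number of prey) and the in-degree its
vulnerability (number of predators).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FoodWeb",
    "JointDegreeSequence",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
    "connectance",
    "joint_degree_sequence",
]


@dataclass
class FoodWeb:
    """A directed Boolean food web.

    Parameters
    ----------
    species
        Ordered species labels, length S.
    adjacency
        S x S Boolean matrix; ``adjacency[i, j]`` is True when species
        ``species[i]`` preys on ``species[j]``.
    """

    species: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.species = list(self.species)
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {a.shape}")
        if len(self.species) != a.shape[0]:
            raise ValueError(
                f"{len(self.species)} species labels for a {a.shape[0]}x{a.shape[1]} matrix"
            )
        if len(self.species) < 1:
            raise ValueError("a food web needs at least one species")
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be unique")
        self.adjacency = a.astype(bool)

    @property
    def S(self) -> int:
        """Number of species."""
        return len(self.species)

    @property
    def L(self) -> int:
        """Number of interactions (1-entries, diagonal included)."""
        return int(self.adjacency.sum())

    @property
    def k_out(self) -> np.ndarray:
        """Generality: number of prey per species (row sums)."""
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def k_in(self) -> np.ndarray:
        """Vulnerability: number of predators per species (column sums)."""
        return self.adjacency.sum(axis=0).astype(int)

    def copy(self) -> "FoodWeb":
        return FoodWeb(list(self.species), self.adjacency.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodWeb):
            return NotImplemented
        return self.species == other.species and bool(
            np.array_equal(self.adjacency, other.adjacency)
        )


@dataclass
class JointDegreeSequence:
    """Per-species (k_in, k_out) pairs: predators and prey counts."""

    k_in: np.ndarray
    k_out: np.ndarray

    def __post_init__(self) -> None:
        self.k_in = np.asarray(self.k_in, dtype=int)
        self.k_out = np.asarray(self.k_out, dtype=int)
        if self.k_in.shape != self.k_out.shape or self.k_in.ndim != 1:
            raise ValueError("k_in and k_out must be 1-D arrays of equal length")
        if (self.k_in < 0).any() or (self.k_out < 0).any():
            raise ValueError("degrees must be non-negative")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "JointDegreeSequence":
        arr = np.array(list(pairs), dtype=int).reshape(-1, 2)
        return cls(arr[:, 0], arr[:, 1])

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(int(a), int(b)) for a, b in zip(self.k_in, self.k_out)]

    def __len__(self) -> int:
        return len(self.k_in)

    @property
    def total_links(self) -> int:
        return int(self.k_in.sum())


def _species_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".species")


def read_edge_list(
    path: str | Path,
    species_list: Sequence[str] | str | Path | None = None,
) -> FoodWeb:
    """Read a predator,prey edge list (CSV or TSV, with header).

    Species order follows first appearance unless ``species_list`` gives
    explicit labels (a sequence, or a path to a one-label-per-line file),
    which may include isolated species. When no explicit list is given and
    a ``<path>.species`` sidecar exists (written by :func:`write_edge_list`),
    it is used so that round-trips preserve species order and isolates.
    Duplicate rows collapse silently: webs are Boolean.
    """
    path = Path(path)
    if species_list is None and _species_sidecar(path).exists():
        species_list = _species_sidecar(path)
    if isinstance(species_list, (str, Path)):
        species_list = [
            line.strip()
            for line in Path(species_list).read_text().splitlines()
            if line.strip()
        ]

    with open(path, newline="") as fh:
        sample = fh.readline()
        delim = "\t" if "\t" in sample else ","
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delim)
        rows = list(reader)
    if not rows:
        raise ValueError(f"{path}: empty file (expected a header row)")
    edges: list[tuple[str, str]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue  # blank line
        if len(row) < 2 or not row[0].strip() or not row[1].strip():
            raise ValueError(f"{path}: malformed row at line {lineno}: {row!r}")
        edges.append((row[0].strip(), row[1].strip()))

    if species_list is not None:
        species = list(species_list)
        known = set(species)
        for pred, prey in edges:
            for sp in (pred, prey):
                if sp not in known:
                    raise ValueError(
                        f"species {sp!r} appears in edges but not in the explicit species list"
                    )
    else:
        species = []
        seen = set()
        for pred, prey in edges:
            for sp in (pred, prey):
                if sp not in seen:
                    seen.add(sp)
                    species.append(sp)
        if not species:
            raise ValueError(
                "edge list has no edges and no explicit species list; "
                "cannot infer the species set"
            )
    index = {sp: i for i, sp in enumerate(species)}
    adj = np.zeros((len(species), len(species)), dtype=bool)
    for pred, prey in edges:
        adj[index[pred], index[prey]] = True
    return FoodWeb(species, adj)


def write_edge_list(web: FoodWeb, path: str | Path, delimiter: str = ",") -> Path:
    """Write ``predator,prey`` rows plus a ``<path>.species`` sidecar.

    The sidecar preserves species order and isolated species so that
    ``read_edge_list(write_edge_list(web))`` is the identity.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["predator", "prey"])
        rows, cols = np.nonzero(web.adjacency)
        for i, j in zip(rows, cols):
            writer.writerow([web.species[i], web.species[j]])
    _species_sidecar(path).write_text("\n".join(web.species) + "\n")
    return path


def read_adjacency(path: str | Path) -> FoodWeb:
    """Read a dense 0/1 adjacency CSV with species labels on both axes."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return FoodWeb([str(s) for s in df.index], df.to_numpy().astype(bool))


def write_adjacency(web: FoodWeb, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        web.adjacency.astype(int), index=web.species, columns=web.species
    )
    df.to_csv(path)
    return path


def connectance(web: FoodWeb) -> float:
    """Fraction of possible interactions realized: L / S^2."""
    return web.L / web.S**2


def joint_degree_sequence(web: FoodWeb) -> JointDegreeSequence:
    """Per-species (k_in, k_out); both sums equal L."""
    return JointDegreeSequence(web.k_in, web.k_out)
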