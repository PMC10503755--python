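"""SVD entropy of Boolean adjacency matrices.

SVD entropy applies Shannon's entropy to the relative non-zero singular
values of a matrix: with singular values sigma_1 >= ... and numerical rank
R, the relative values s_i = sigma_i / sum_{i<=R} sigma_i form a
probability-like vector and

    J = -sum_i s_i ln(s_i).

Standardizing by ln(R) (the maximum J attains when the top-R spectrum is
flat) maps J to [0, 1], comparable across matrix sizes — an evenness-style
normalization. It measures the internal complexity of a network: 1 for
matrices with a flat spectrum (e.g. permutation matrices), low for highly
redundant (nested/low-rank) structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SingularSpectrum", "singular_spectrum", "svd_entropy"]

#: singular values below RANK_TOL * sigma_max count as zero
RANK_TOL = 1e-10


@dataclass
class SingularSpectrum:
    sigma: np.ndarray  # all singular values, non-increasing
    R: int  # numerical rank
    s: np.ndarray  # relative singular values over the top R; sums to 1


def singular_spectrum(matrix: np.ndarray) -> SingularSpectrum:
    """Singular values, numerical rank, and relative spectrum of a matrix."""
    a = np.asarray(matrix, dtype=float)
    if a.size == 0:
        raise ValueError("empty matrix")
    sigma = np.linalg.svd(a, compute_uv=False)
    if sigma[0] <= 0:
        raise ValueError("all-zero matrix: rank 0, entropy undefined")
    R = int((sigma > RANK_TOL * sigma[0]).sum())
    top = sigma[:R]
    return SingularSpectrum(sigma=sigma, R=R, s=top / top.sum())


def svd_entropy(matrix: np.ndarray, standardized: bool = True) -> float:
    """SVD entropy J = -sum s_i ln s_i, optionally standardized by ln(rank).

    A rank-1 matrix has raw J = 0; its standardized value is defined as 0
    (the degenerate limit of J/ln R — minimal complexity).
    """
    spec = singular_spectrum(matrix)
    s = spec.s[spec.s > 0]
    J = float(-(s * np.log(s)).sum())
    if not standardized:
        return J
    if spec.R == 1:
        return 0.0
    return J / np.log(spec.R)
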