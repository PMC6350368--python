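"""Gaussian interaction-profile kernel and integrated miRNA similarity.

Each miRNA's *interaction profile* IP(m(i)) is its binary row of the
association matrix A — the pattern of diseases it is known to associate
with.  Two miRNAs with similar profiles get a high Gaussian kernel value

    GM(i, j) = exp(-gamma_m * ||IP(m(i)) - IP(m(j))||^2),

with the bandwidth gamma_m obtained by normalizing a raw bandwidth
gamma'_m by the mean squared profile norm (for binary profiles, the average
number of known associations per miRNA).  The integrated similarity SM
takes the curated functional similarity FS wherever a pair has one, and
falls back to GM otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AssociationMatrix, SimilarityMatrix

DEFAULT_GAMMA_PRIME = 1.0  # standard choice in the interaction-profile kernel literature


@dataclass(frozen=True)
class KernelParams:
    """Raw and normalized bandwidth of the interaction-profile kernel."""

    gamma_prime: float
    gamma: float

    def __post_init__(self) -> None:
        if self.gamma_prime <= 0:
            raise ValueError("gamma_prime must be positive")
        if not np.isfinite(self.gamma) or self.gamma <= 0:
            raise ValueError("normalized bandwidth must be finite and positive")


def compute_bandwidth(assoc: AssociationMatrix, gamma_prime: float = DEFAULT_GAMMA_PRIME) -> float:
    """Normalize ``gamma_prime`` by the mean squared interaction-profile norm.

    For a binary adjacency the squared norm of a profile is its row sum, so
    the denominator is the average number of known disease associations per
    miRNA.
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    sq_norms = np.asarray(assoc.A, dtype=float).sum(axis=1)
    mean_sq = sq_norms.mean() if sq_norms.size else 0.0
    if mean_sq == 0:
        raise ValueError("no associations: bandwidth undefined")
    return gamma_prime / mean_sq


def gaussian_profile_kernel(assoc: AssociationMatrix, gamma: float) -> SimilarityMatrix:
    """Gaussian kernel on interaction profiles (role GM).

    Computed from the squared-distance expansion
    ``||a - b||^2 = ||a||^2 + ||b||^2 - 2 a.b``; the diagonal is pinned to
    exactly 1 to avoid round-off drift.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    A = np.asarray(assoc.A, dtype=float)
    sq = (A * A).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (A @ A.T)
    np.maximum(d2, 0.0, out=d2)
    GM = np.exp(-gamma * d2)
    GM = (GM + GM.T) / 2.0
    np.fill_diagonal(GM, 1.0)
    return SimilarityMatrix(list(assoc.mirna_ids), GM, role="GM")


def integrate_similarity(fs: SimilarityMatrix, gm: SimilarityMatrix) -> SimilarityMatrix:
    """Integrated similarity SM: FS where a pair has functional similarity, GM otherwise.

    The diagonal takes the FS self-similarity where defined, 1 otherwise
    (both conventions give unit self-similarity, and downstream column
    normalization relies on a positive diagonal).
    """
    if fs.S.shape != gm.S.shape or fs.mirna_ids != gm.mirna_ids:
        raise ValueError("FS and GM must be aligned to the same miRNA order")
    SM = np.where(fs.defined_mask, fs.S, gm.S)
    diag = np.where(np.diag(fs.defined_mask), np.diag(fs.S), 1.0)
    np.fill_diagonal(SM, diag)
    SM = (SM + SM.T) / 2.0
    return SimilarityMatrix(list(fs.mirna_ids), SM, role="SM")


def integrated_similarity(
    assoc: AssociationMatrix,
    fs: SimilarityMatrix,
    gamma_prime: float = DEFAULT_GAMMA_PRIME,
) -> SimilarityMatrix:
    """Convenience chain: bandwidth -> Gaussian kernel -> integration."""
    gamma = compute_bandwidth(assoc, gamma_prime)
    gm = gaussian_profile_kernel(assoc, gamma)
    return integrate_similarity(fs, gm)
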