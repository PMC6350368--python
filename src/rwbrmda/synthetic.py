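"""Planted-structure synthetic fixtures: associations + functional similarity.

The generator realizes the method's core assumption — functionally similar
miRNAs tend to associate with the same diseases — as aligned bipartite
communities: miRNAs and diseases are partitioned into the same blocks,
associations are Bernoulli with a higher probability inside a block than
across, and functional similarity values are drawn around a high
within-block mean and a low cross-block mean with Gaussian noise, clipped
to [0, 1].  A coverage fraction of off-diagonal pairs keeps a defined FS
value; the rest are masked undefined, exercising the fall-back to the
Gaussian kernel in the integration step.

Everything is reproducible from the single integer seed.  The generator
makes no attempt to mimic the degree distribution of real curated
association databases; see docs/methods.md for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_io import AssociationMatrix, SimilarityMatrix


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted block fixture (defaults = study conditions)."""

    n_mirna: int = 150
    n_disease: int = 30
    n_blocks: int = 3
    within_block_assoc_prob: float = 0.6
    cross_block_assoc_prob: float = 0.05
    fs_within_mean: float = 0.8
    fs_cross_mean: float = 0.2
    fs_noise_sd: float = 0.05
    fs_coverage: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "within_block_assoc_prob", "cross_block_assoc_prob",
            "fs_within_mean", "fs_cross_mean", "fs_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fs_noise_sd < 0:
            raise ValueError("fs_noise_sd must be nonnegative")
        if self.n_blocks < 1 or self.n_blocks > min(self.n_mirna, self.n_disease):
            raise ValueError("n_blocks must be in [1, min(n_mirna, n_disease)]")

    def with_signal(self, within_block_assoc_prob: float) -> "FixtureSpec":
        return replace(self, within_block_assoc_prob=within_block_assoc_prob)


def _block_assignment(n: int, n_blocks: int) -> np.ndarray:
    # contiguous, nearly equal blocks; stable under the zero-padded id order
    return np.repeat(np.arange(n_blocks), np.diff(np.linspace(0, n, n_blocks + 1).astype(int)))


def generate(
    spec: FixtureSpec,
) -> tuple[AssociationMatrix, SimilarityMatrix, np.ndarray]:
    """Draw one fixture; returns (associations, FS, miRNA block assignment).

    Identifiers are zero-padded so lexicographic canonical order equals
    generation order, keeping block assignments aligned downstream.
    """
    rng = np.random.default_rng(spec.seed)
    width_m = len(str(spec.n_mirna - 1))
    width_d = len(str(spec.n_disease - 1))
    mirna_ids = [f"mir-{i:0{width_m}d}" for i in range(spec.n_mirna)]
    disease_ids = [f"disease-{j:0{width_d}d}" for j in range(spec.n_disease)]
    m_blocks = _block_assignment(spec.n_mirna, spec.n_blocks)
    d_blocks = _block_assignment(spec.n_disease, spec.n_blocks)

    same_block = m_blocks[:, None] == d_blocks[None, :]
    prob = np.where(same_block, spec.within_block_assoc_prob, spec.cross_block_assoc_prob)
    A = (rng.random((spec.n_mirna, spec.n_disease)) < prob).astype(np.int8)
    assoc = AssociationMatrix(mirna_ids, disease_ids, A)

    same_mm = m_blocks[:, None] == m_blocks[None, :]
    mean = np.where(same_mm, spec.fs_within_mean, spec.fs_cross_mean)
    noise = rng.normal(0.0, spec.fs_noise_sd, size=(spec.n_mirna, spec.n_mirna))
    S = np.clip(mean + noise, 0.0, 1.0)
    S = np.triu(S, 1)
    S = S + S.T
    np.fill_diagonal(S, 1.0)
    covered = rng.random((spec.n_mirna, spec.n_mirna)) < spec.fs_coverage
    covered = np.triu(covered, 1)
    mask = covered | covered.T
    np.fill_diagonal(mask, True)
    S = np.where(mask, S, 0.0)
    fs = SimilarityMatrix(mirna_ids, S, defined_mask=mask, role="FS")
    return assoc, fs, m_blocks


def shuffle_labels(assoc: AssociationMatrix, seed: int) -> AssociationMatrix:
    """Null model: permute each disease's label column independently.

    Every disease keeps its number of known miRNAs, but which miRNAs carry
    the labels is random, so neither the functional similarity nor the
    interaction-profile kernel predicts them.
    """
    rng = np.random.default_rng(seed)
    A = np.empty_like(assoc.A)
    for j in range(assoc.n_disease):
        A[:, j] = assoc.A[rng.permutation(assoc.n_mirna), j]
    return AssociationMatrix(list(assoc.mirna_ids), list(assoc.disease_ids), A)
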