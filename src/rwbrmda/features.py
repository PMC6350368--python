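"""Ternary feature extraction from stationary walk profiles.

For a disease d with binary label vector y (its column of the association
matrix), every miRNA i gets the feature vector

    Vec(m(i)) = (1, phi_i1, phi_i0),

where phi_i1 sums the stationary probabilities of miRNA i's top-K ranked
candidate miRNAs that carry label 1 for d, and phi_i0 sums those with
label 0.  K defaults to 50 (about 10% of the miRNA count in the reference
association data); for small networks it falls back to ceil(0.1 * n).
The seed itself is excluded from its candidate list so its own label never
leaks into its feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .random_walk import StationaryProfile

DEFAULT_TOP_K = 50


@dataclass(frozen=True)
class FeatureVector:
    """(1, phi1, phi0) for one miRNA with respect to one disease."""

    mirna_index: int
    phi1: float
    phi0: float

    constant: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.constant, self.phi1, self.phi0])


def default_top_k(n_mirna: int) -> int:
    """K = 50 when the network is large enough, else about 10% of the nodes."""
    if n_mirna > DEFAULT_TOP_K:
        return DEFAULT_TOP_K
    return max(1, math.ceil(0.1 * n_mirna))


def top_k_candidates(profile: StationaryProfile, k: int) -> np.ndarray:
    """Indices of the k candidates with largest stationary probability.

    The seed is excluded; ties break by canonical (ascending index) order.
    """
    p = profile.p_inf
    n = p.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of miRNAs ({n})")
    candidates = np.arange(n)
    if 0 <= profile.seed_index < n:
        candidates = candidates[candidates != profile.seed_index]
    # stable sort on descending probability keeps ascending-index tie order
    order = candidates[np.argsort(-p[candidates], kind="stable")]
    return order[:k]


def build_features(
    profiles: list[StationaryProfile], labels: np.ndarray, k: int
) -> list[FeatureVector]:
    """Feature vector for every miRNA with respect to one disease's labels."""
    labels = np.asarray(labels)
    n = len(profiles)
    if labels.shape[0] != n:
        raise ValueError("label vector length must equal the number of miRNAs")
    out = []
    for i, profile in enumerate(profiles):
        cand = top_k_candidates(profile, k)
        mass = profile.p_inf[cand]
        pos = labels[cand] == 1
        out.append(FeatureVector(i, phi1=float(mass[pos].sum()), phi0=float(mass[~pos].sum())))
    return out


def feature_matrix(features: list[FeatureVector]) -> np.ndarray:
    """Design matrix X with columns (1, phi1, phi0), rows in miRNA order."""
    return np.array([[f.constant, f.phi1, f.phi0] for f in features])


def write_feature_table(
    features: list[FeatureVector], mirna_ids: list[str], labels, path, delimiter: str = "\t"
) -> None:
    """Export per-miRNA features and labels as TSV (mirna_id, phi1, phi0, label)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(delimiter.join(["mirna_id", "phi1", "phi0", "label"]) + "\n")
        for f in features:
            handle.write(
                delimiter.join(
                    [mirna_ids[f.mirna_index], f"{f.phi1:.12g}", f"{f.phi0:.12g}",
                     str(int(labels[f.mirna_index]))]
                ) + "\n"
            )


def candidate_table(profiles: list[StationaryProfile], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Precompute (n x k) candidate indices and masses for repeated labelings.

    Useful in leave-one-out evaluation where labels change per fold but the
    walk profiles do not.
    """
    idx = np.vstack([top_k_candidates(p, k) for p in profiles])
    mass = np.vstack([p.p_inf[row] for p, row in zip(profiles, idx)])
    return idx, mass


def features_from_table(
    cand_idx: np.ndarray, cand_mass: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Vectorized design matrix from a precomputed candidate table."""
    pos = labels[cand_idx] == 1
    phi1 = np.where(pos, cand_mass, 0.0).sum(axis=1)
    phi0 = np.where(pos, 0.0, cand_mass).sum(axis=1)
    return np.column_stack([np.ones_like(phi1), phi1, phi0])
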