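"""Random walk with restart (RWR) on the integrated miRNA similarity network.

Every miRNA in turn is the walk's seed.  The update is

    p(t+1) = (1 - r) * T p(t) + r * p(0),

where T is the column-normalized integrated similarity SM (normalization is
required for p to stay a probability vector), r is the restart probability,
and p(0) is the normalized seed row of SM.  Iteration stops when the L1
change between successive vectors drops below the cutoff (default 1e-6).
The fixed point is the unique solution of p = r (I - (1-r) T)^-1 p(0), which
serves as the independent oracle in the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import SimilarityMatrix

logger = logging.getLogger("rwbrmda")

DEFAULT_RESTART = 0.7  # not fixed by the method's description; see docs/methods.md
DEFAULT_CUTOFF = 1e-6
DEFAULT_MAX_ITER = 10_000


@dataclass(frozen=True)
class WalkParams:
    restart: float = DEFAULT_RESTART
    cutoff: float = DEFAULT_CUTOFF
    max_iter: int = DEFAULT_MAX_ITER

    def __post_init__(self) -> None:
        if not 0.0 < self.restart < 1.0:
            raise ValueError("restart probability must lie strictly in (0, 1)")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")


@dataclass
class StationaryProfile:
    """Converged RWR distribution over all miRNAs for one seed miRNA."""

    seed_index: int
    p_inf: np.ndarray
    iterations: int
    final_delta: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.p_inf = np.asarray(self.p_inf, dtype=float)
        if (self.p_inf < -1e-12).any():
            raise ValueError("stationary probabilities must be nonnegative")
        if abs(self.p_inf.sum() - 1.0) > 1e-9:
            raise ValueError("stationary probabilities must sum to 1")


def transition_matrix(sm: SimilarityMatrix) -> np.ndarray:
    """Column-normalize SM: entry (i, j) = SM(i, j) / sum_k SM(k, j)."""
    S = np.asarray(sm.S, dtype=float)
    col_sums = S.sum(axis=0)
    zero = np.flatnonzero(col_sums <= 0)
    if zero.size:
        names = ", ".join(sm.mirna_ids[i] for i in zero[:5])
        raise ValueError(f"zero similarity column for miRNA(s): {names}")
    return S / col_sums[None, :]


def initial_distribution(sm: SimilarityMatrix, seed_index: int) -> np.ndarray:
    """p(0): the seed miRNA's row of SM, normalized to sum 1."""
    row = np.asarray(sm.S[seed_index], dtype=float)
    total = row.sum()
    if total <= 0:
        raise ValueError(f"zero similarity row for miRNA {sm.mirna_ids[seed_index]!r}")
    return row / total


def walk_to_stationary(
    T: np.ndarray, p0: np.ndarray, params: WalkParams, seed_index: int = -1
) -> StationaryProfile:
    """Power-iterate the RWR update from p0 until the L1 change < cutoff."""
    p = np.asarray(p0, dtype=float)
    r = params.restart
    restart_term = r * p
    delta = np.inf
    for it in range(1, params.max_iter + 1):
        p_next = (1.0 - r) * (T @ p) + restart_term
        delta = float(np.abs(p_next - p).sum())
        p = p_next
        if delta < params.cutoff:
            return StationaryProfile(seed_index, p, iterations=it, final_delta=delta)
    logger.warning(
        "RWR from seed %d did not converge in %d iterations (last L1 change %.3g)",
        seed_index, params.max_iter, delta,
    )
    return StationaryProfile(
        seed_index, p, iterations=params.max_iter, final_delta=delta, converged=False
    )


def stationary_solve(T: np.ndarray, p0: np.ndarray, restart: float) -> np.ndarray:
    """Direct linear solve of the RWR fixed point (oracle for the iteration)."""
    n = T.shape[0]
    return restart * np.linalg.solve(np.eye(n) - (1.0 - restart) * T, np.asarray(p0, float))


def walk_all_to_stationary(
    T: np.ndarray, P0: np.ndarray, params: WalkParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run many walks at once; column s of P0 is seed s's initial distribution.

    Per-column results match :func:`walk_to_stationary` up to floating-point
    associativity (each column is frozen the moment its own L1 change drops
    below the cutoff); the updates are batched into matrix products.  Returns (P_inf, iterations,
    final_deltas).
    """
    r = params.restart
    n, m = P0.shape
    P = P0.copy()
    iters = np.full(m, params.max_iter, dtype=int)
    deltas = np.full(m, np.inf)
    active = np.arange(m)
    for it in range(1, params.max_iter + 1):
        block = P[:, active]
        new = (1.0 - r) * (T @ block) + r * P0[:, active]
        d = np.abs(new - block).sum(axis=0)
        P[:, active] = new
        done = d < params.cutoff
        iters[active[done]] = it
        deltas[active] = d
        active = active[~done]
        if active.size == 0:
            return P, iters, deltas
    logger.warning(
        "RWR: %d of %d walks did not converge in %d iterations",
        active.size, m, params.max_iter,
    )
    return P, iters, deltas


def all_walks(sm: SimilarityMatrix, params: WalkParams) -> list[StationaryProfile]:
    """One converged walk per miRNA, seeds in canonical identifier order."""
    T = transition_matrix(sm)
    P0 = np.column_stack([initial_distribution(sm, i) for i in range(sm.n_mirna)])
    P, iters, deltas = walk_all_to_stationary(T, P0, params)
    return [
        StationaryProfile(
            i, P[:, i], iterations=int(iters[i]), final_delta=float(deltas[i]),
            converged=bool(deltas[i] < params.cutoff),
        )
        for i in range(sm.n_mirna)
    ]


def profiles_to_matrix(profiles: list[StationaryProfile]) -> np.ndarray:
    """Stack stationary vectors into a (seed x node) matrix."""
    return np.vstack([p.p_inf for p in profiles])


def write_profiles(
    profiles: list[StationaryProfile], mirna_ids: list[str], path, delimiter: str = "\t"
) -> None:
    """Export the dense (seed x node) stationary matrix as labelled TSV."""
    import pandas as pd

    pd.DataFrame(profiles_to_matrix(profiles), index=mirna_ids, columns=mirna_ids).to_csv(
        path, sep=delimiter, float_format="%.12g", index_label="seed"
    )
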