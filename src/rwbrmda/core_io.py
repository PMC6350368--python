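"""Readers, writers and containers for association and similarity data.

The two on-disk formats are deliberately minimal plain text:

* associations — two-column delimited text ``(mirna_id, disease_id)``, one
  record per evidence line, optional header;
* similarity — a square delimited matrix whose first row and first column
  carry the miRNA labels; an empty cell means "no value for this pair".

Identifiers are normalized (lower-cased, whitespace-trimmed) before any
matching, because the public miRNA resources disagree on capitalization and
a silently misaligned row is the worst failure mode this package can have.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rwbrmda")

#: tolerance for accepting (and averaging away) asymmetry in a similarity file
ASYMMETRY_TOL = 1e-6

_HEADER_TOKENS = {
    "mirna", "mirna_id", "mir", "mir_id", "mirna_name", "name",
    "disease", "disease_id", "disease_name", "id",
}


def normalize_id(identifier: str) -> str:
    """Canonical form of an identifier: stripped and lower-cased."""
    return identifier.strip().lower()


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease adjacency matrix with identifier labels.

    ``A[i, j] == 1`` iff miRNA ``mirna_ids[i]`` is associated with disease
    ``disease_ids[j]``.  The identifier order here is the canonical order for
    every downstream matrix and vector.
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError(
                f"adjacency shape {self.A.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.disease_ids)} diseases"
            )
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def disease_index(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(normalize_id(disease_id))
        except ValueError:
            raise KeyError(f"unknown disease identifier: {disease_id!r}") from None


@dataclass
class SimilarityMatrix:
    """Square symmetric miRNA x miRNA similarity with a per-entry defined mask.

    ``role`` records which similarity this is: ``"FS"`` (functional
    similarity, possibly with undefined pairs), ``"GM"`` (Gaussian
    interaction-profile kernel, always fully defined) or ``"SM"``
    (integrated similarity).
    """

    mirna_ids: list[str]
    S: np.ndarray
    defined_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    role: str = "FS"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.mirna_ids)
        if self.S.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.S.shape} is not {n}x{n}")
        if self.defined_mask is None:
            self.defined_mask = np.ones((n, n), dtype=bool)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
        if self.defined_mask.shape != (n, n):
            raise ValueError("defined_mask shape does not match matrix")
        if not np.array_equal(self.defined_mask, self.defined_mask.T):
            raise ValueError("defined_mask must be symmetric")
        defined = self.defined_mask
        if defined.any():
            vals = self.S[defined]
            if np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12:
                raise ValueError("defined similarity entries must lie in [0, 1]")
            asym = np.abs(self.S - self.S.T)[defined & defined.T]
            if asym.size and asym.max() > 1e-12:
                raise ValueError("similarity matrix not symmetric on defined entries")

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)


def read_associations(path, delimiter: str = "\t") -> AssociationMatrix:
    """Read a two-column association list into an :class:`AssociationMatrix`.

    Duplicate records (one row per piece of evidence is common in curated
    databases) collapse to a single entry; identifier lists are sorted
    lexicographically after normalization so the result does not depend on
    input line order.
    """
    pairs: set[tuple[str, str]] = set()
    n_records = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(delimiter)
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: line {lineno}: expected two non-empty fields "
                    f"(mirna, disease), got {line!r}"
                )
            pairs.add((normalize_id(fields[0]), normalize_id(fields[1])))
            n_records += 1
    if not pairs:
        raise ValueError(f"{path}: no association records found")
    if n_records > len(pairs):
        logger.info("collapsed %d duplicate association records", n_records - len(pairs))
    mirna_ids = sorted({m for m, _ in pairs})
    disease_ids = sorted({d for _, d in pairs})
    mi = {m: i for i, m in enumerate(mirna_ids)}
    di = {d: j for j, d in enumerate(disease_ids)}
    A = np.zeros((len(mirna_ids), len(disease_ids)), dtype=np.int8)
    for m, d in pairs:
        A[mi[m], di[d]] = 1
    return AssociationMatrix(mirna_ids, disease_ids, A)


def _looks_like_header(fields: list[str]) -> bool:
    return all(normalize_id(f) in _HEADER_TOKENS for f in fields[:2])


def read_similarity(path, delimiter: str = "\t") -> SimilarityMatrix:
    """Read a labelled square similarity matrix (role FS).

    Blank cells are recorded as undefined.  A value present on only one side
    of the diagonal is mirrored; a pair present on both sides is averaged,
    provided the two values agree within :data:`ASYMMETRY_TOL`.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, header=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity matrix is not square: {df.shape}")
    rows = [normalize_id(str(r)) for r in df.index]
    cols = [normalize_id(str(c)) for c in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: row labels and column labels disagree")
    try:
        S = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in similarity matrix: {exc}") from exc
    present = ~np.isnan(S)
    both = present & present.T
    asym = np.abs(S - S.T)[both]
    if asym.size and np.nanmax(asym) > ASYMMETRY_TOL:
        raise ValueError(
            f"{path}: similarity matrix asymmetric beyond {ASYMMETRY_TOL:g} "
            f"(max |S - S.T| = {np.nanmax(asym):.3g})"
        )
    # mirror one-sided values, average two-sided ones
    with np.errstate(invalid="ignore"):
        sym = np.where(both, (S + S.T) / 2.0, np.where(present, S, S.T))
    mask = present | present.T
    sym = np.where(mask, sym, 0.0)
    return SimilarityMatrix(rows, sym, defined_mask=mask, role="FS")


def write_similarity(sim: SimilarityMatrix, path, delimiter: str = "\t") -> None:
    """Write a similarity matrix in the format :func:`read_similarity` reads."""
    values = np.where(sim.defined_mask, sim.S, np.nan)
    df = pd.DataFrame(values, index=sim.mirna_ids, columns=sim.mirna_ids)
    df.to_csv(path, sep=delimiter, float_format="%.12g", na_rep="")


def write_associations(assoc: AssociationMatrix, path, delimiter: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"mirna_id{delimiter}disease_id\n")
        for i, j in zip(*np.nonzero(assoc.A)):
            handle.write(f"{assoc.mirna_ids[i]}{delimiter}{assoc.disease_ids[j]}\n")


def align(
    assoc: AssociationMatrix, fs: SimilarityMatrix
) -> tuple[AssociationMatrix, SimilarityMatrix]:
    """Put the association matrix and FS on a common miRNA order.

    The association matrix defines the universe: miRNAs absent from FS are
    retained with fully undefined FS rows (the integration step then falls
    back to the Gaussian kernel for those pairs); FS-only miRNAs are dropped.
    """
    shared = set(assoc.mirna_ids) & set(fs.mirna_ids)
    if assoc.n_mirna == 0:
        raise ValueError("empty miRNA intersection and empty FS: nothing to integrate")
    if not shared and fs.n_mirna > 0:
        logger.warning("no miRNA shared between associations and FS; FS is unused")

    order = assoc.mirna_ids  # already canonical (sorted, normalized)
    n = len(order)
    fs_index = {m: i for i, m in enumerate(fs.mirna_ids)}
    S = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    kept = 0
    for a, ma in enumerate(order):
        ia = fs_index.get(ma)
        if ia is None:
            continue
        kept += 1
        for b, mb in enumerate(order):
            ib = fs_index.get(mb)
            if ib is not None and fs.defined_mask[ia, ib]:
                S[a, b] = fs.S[ia, ib]
                mask[a, b] = True
    dropped = fs.n_mirna - kept
    logger.info(
        "aligned FS to association order: %d miRNAs kept, %d FS-only dropped, "
        "%d without FS coverage", kept, dropped, n - kept
    )
    return assoc, SimilarityMatrix(list(order), S, defined_mask=mask, role="FS")
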