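"""End-to-end predictor and leave-one-out cross-validation (LOOCV).

Prediction for one disease chains the whole method: the disease's column of
the association matrix provides binary labels, the stationary walk profiles
provide the ternary features, a logistic regression is fit on all miRNAs,
and every label-0 miRNA (candidate) is ranked by its posterior association
probability.

LOOCV removes each known association (i, j) in turn, re-labels, re-extracts
features and refits the regression, and records where the held-out miRNA
ranks among disease j's candidates.  Folds are pooled into one ROC curve by
sweeping a threshold on the normalized rank: calling the top fraction q of
each fold's candidate list "positive" gives FPR exactly q, and TPR the
fraction of held-out miRNAs recovered at that depth.  The area under this
curve equals the mean per-fold tie-corrected Mann-Whitney statistic.

By default the similarity network and the walk profiles are computed once
from the full association matrix and held fixed across folds; only labels,
features and the regression are per-fold.  ``strict=True`` recomputes
everything (Gaussian kernel, integration, all walks) inside every fold,
which is exact but quadratically slower and practical only for small data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import regression
from .core_io import AssociationMatrix, SimilarityMatrix
from .features import candidate_table, default_top_k, features_from_table
from .random_walk import StationaryProfile, WalkParams, all_walks
from .similarity import DEFAULT_GAMMA_PRIME, integrated_similarity

logger = logging.getLogger("rwbrmda")


@dataclass(frozen=True)
class PipelineParams:
    """All tunables of the method in one place (see docs/methods.md)."""

    gamma_prime: float = DEFAULT_GAMMA_PRIME
    restart: float = 0.7
    cutoff: float = 1e-6
    max_iter: int = 10_000
    top_k: int | None = None  # None -> 50 or ~10% of miRNAs for small networks
    tol: float = 1e-8
    ridge: float = 1e-8

    def walk_params(self) -> WalkParams:
        return WalkParams(self.restart, self.cutoff, self.max_iter)

    def resolve_k(self, n_mirna: int) -> int:
        return self.top_k if self.top_k is not None else default_top_k(n_mirna)


@dataclass
class DiseasePrediction:
    """Ranked candidate miRNAs for one disease."""

    disease_id: str
    ranked: list[tuple[str, float, int]]  # (mirna_id, score, rank) descending score
    training_positives: list[str]
    model: regression.RegressionModel

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranked, columns=["mirna_id", "score", "rank"]).assign(
            disease_id=self.disease_id
        )[["disease_id", "mirna_id", "score", "rank"]]


@dataclass(frozen=True)
class FoldRecord:
    """Placement of one held-out association among its disease's candidates."""

    mirna_id: str
    disease_id: str
    n_greater: int  # candidates scored strictly above the test miRNA
    n_tie: int      # candidates with exactly the test score
    n_candidates: int  # candidates excluding the test miRNA

    @property
    def normalized_rank(self) -> float:
        """Fraction of candidates ranked above the test (ties count half)."""
        return (self.n_greater + 0.5 * self.n_tie) / self.n_candidates

    @property
    def mann_whitney(self) -> float:
        return 1.0 - self.normalized_rank


@dataclass
class RocResult:
    folds: list[FoldRecord]
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_skipped: int = 0

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def mann_whitney_auc(self) -> float:
        """Mean per-fold tie-corrected Mann-Whitney statistic (pairwise oracle form)."""
        return float(np.mean([f.mann_whitney for f in self.folds]))


def compute_profiles(
    assoc: AssociationMatrix, fs: SimilarityMatrix, params: PipelineParams
) -> tuple[SimilarityMatrix, list[StationaryProfile]]:
    """Integrated similarity and one converged walk per miRNA."""
    sm = integrated_similarity(assoc, fs, params.gamma_prime)
    return sm, all_walks(sm, params.walk_params())


def _rank_candidates(
    assoc: AssociationMatrix, scores: np.ndarray, labels: np.ndarray
) -> list[tuple[str, float, int]]:
    cand = np.flatnonzero(labels == 0)
    order = cand[np.argsort(-scores[cand], kind="stable")]  # ties: canonical id order
    return [
        (assoc.mirna_ids[i], float(scores[i]), rank)
        for rank, i in enumerate(order, start=1)
    ]


def predict_disease(
    assoc: AssociationMatrix,
    profiles: list[StationaryProfile],
    disease_id: str,
    params: PipelineParams = PipelineParams(),
) -> DiseasePrediction:
    """Score and rank all unlabelled miRNAs for one disease."""
    j = assoc.disease_index(disease_id)
    labels = np.asarray(assoc.A[:, j], dtype=int)
    if labels.sum() == 0:
        raise ValueError(
            f"disease {disease_id!r} has no known associations; model cannot be trained"
        )
    k = params.resolve_k(assoc.n_mirna)
    cand_idx, cand_mass = candidate_table(profiles, k)
    X = features_from_table(cand_idx, cand_mass, labels)
    model = regression.fit(X, labels, tol=params.tol, ridge=params.ridge)
    scores = regression.predict(model, X)
    return DiseasePrediction(
        disease_id=assoc.disease_ids[j],
        ranked=_rank_candidates(assoc, scores, labels),
        training_positives=[assoc.mirna_ids[i] for i in np.flatnonzero(labels == 1)],
        model=model,
    )


def roc_from_folds(folds: list[FoldRecord], n_skipped: int = 0) -> RocResult:
    """Pool folds into a rank-threshold ROC (staircase with explicit verticals).

    The x axis is the normalized rank threshold q (the fraction of each
    fold's candidate list called positive, hence the FPR); the y axis is the
    fraction of folds whose held-out miRNA is recovered at depth q.
    """
    if not folds:
        raise ValueError("no LOOCV folds to pool")
    ranks = np.array([f.normalized_rank for f in folds])
    qs = np.unique(ranks)
    F = len(folds)
    fpr = [0.0]
    tpr = [0.0]
    t0 = float((ranks <= 0.0).sum()) / F
    if t0 > 0.0:
        fpr.append(0.0)
        tpr.append(t0)
    for q in qs:
        if q == 0.0:
            continue
        t = float((ranks <= q).sum()) / F
        fpr.extend([q, q])
        tpr.extend([tpr[-1], t])
    if fpr[-1] < 1.0:
        fpr.append(1.0)
        tpr.append(1.0)
    fpr_a, tpr_a = np.array(fpr), np.array(tpr)
    auc = float(np.trapezoid(tpr_a, fpr_a))
    return RocResult(folds, fpr_a, tpr_a, auc, n_skipped=n_skipped)


def loocv(
    assoc: AssociationMatrix,
    fs: SimilarityMatrix,
    params: PipelineParams = PipelineParams(),
    strict: bool = False,
) -> RocResult:
    """Leave each known association out in turn and pool the test ranks."""
    A = np.asarray(assoc.A, dtype=int)
    pairs = list(zip(*np.nonzero(A)))
    folds: list[FoldRecord] = []
    n_skipped = 0
    k = params.resolve_k(assoc.n_mirna)

    if not strict:
        _, profiles = compute_profiles(assoc, fs, params)
        cand_idx, cand_mass = candidate_table(profiles, k)

    for i, j in pairs:
        labels = A[:, j].copy()
        labels[i] = 0
        if labels.sum() == 0:
            n_skipped += 1  # disease lost its last seed sample; untrainable fold
            continue
        if strict:
            A_fold = A.copy()
            A_fold[i, j] = 0
            assoc_fold = AssociationMatrix(assoc.mirna_ids, assoc.disease_ids, A_fold)
            _, profiles_fold = compute_profiles(assoc_fold, fs, params)
            ci, cm = candidate_table(profiles_fold, k)
        else:
            ci, cm = cand_idx, cand_mass
        X = features_from_table(ci, cm, labels)
        model = regression.fit(X, labels, tol=params.tol, ridge=params.ridge)
        scores = regression.predict(model, X)
        others = np.flatnonzero(labels == 0)
        others = others[others != i]
        s = scores[i]
        folds.append(
            FoldRecord(
                mirna_id=assoc.mirna_ids[i],
                disease_id=assoc.disease_ids[j],
                n_greater=int((scores[others] > s).sum()),
                n_tie=int((scores[others] == s).sum()),
                n_candidates=len(others),
            )
        )
    if n_skipped:
        logger.info("LOOCV: skipped %d folds whose disease lost its last positive", n_skipped)
    return roc_from_folds(folds, n_skipped=n_skipped)


def _safe_filename(disease_id: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", disease_id).strip("_") or "disease"


def predict_all(
    assoc: AssociationMatrix,
    fs: SimilarityMatrix,
    params: PipelineParams = PipelineParams(),
    out_dir: str | Path | None = None,
) -> dict[str, DiseasePrediction]:
    """Ranked candidate table for every disease with at least one positive.

    With ``out_dir`` set, writes one TSV per disease plus a combined
    long-format ``predictions.tsv``.
    """
    _, profiles = compute_profiles(assoc, fs, params)
    results: dict[str, DiseasePrediction] = {}
    for disease_id in assoc.disease_ids:
        try:
            results[disease_id] = predict_disease(assoc, profiles, disease_id, params)
        except ValueError as exc:
            logger.warning("skipping disease %r: %s", disease_id, exc)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frames = []
        for disease_id, pred in results.items():
            frame = pred.to_frame()
            frame.to_csv(out_dir / f"{_safe_filename(disease_id)}.tsv", sep="\t", index=False)
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(
            out_dir / "predictions.tsv", sep="\t", index=False
        )
    return results
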