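"""Cross-validation protocols, ROC/PR metrics and candidate ranking.

Two protocols are implemented:

* **Global fivefold CV** — the known associations are partitioned into
  folds; each fold is zeroed in the training matrix, similarity kernels are
  recomputed from the training matrix only (no leakage through interaction
  profiles), the model is refit, and the held-out positives are scored
  against every pair never labelled positive in the full dataset.  Both the
  per-fold and the pooled (scores concatenated across folds) AUC/AUPR are
  reported.

* **New-disease CV (CV_d)** — for each test disease its whole association
  column is zeroed, the model refit, and all miRNAs ranked for that disease;
  this probes cold-start prediction, where only the disease similarity graph
  can carry signal.  The summary statistic is the mean of per-disease AUCs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_curve

from .factorization import Hyperparams, FactorModel, fit, predict
from .io import AssociationDataset, MeshTable
from .similarity import SimilarityMatrix, disease_similarity, mirna_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "EvaluationReport",
    "RankedCandidates",
    "make_folds",
    "roc_auc",
    "pr_aupr",
    "fold_training_matrix",
    "fold_similarities",
    "run_fivefold",
    "run_cv_d",
    "sweep_lambda",
    "rank_candidates",
]


@dataclass(frozen=True)
class FoldPlan:
    """Seeded partition of the known associations into folds.

    ``pairs`` holds the (miRNA, disease) indices of every positive;
    ``assignment[p]`` is the fold (0-based) of ``pairs[p]``.  Fold sizes
    differ by at most one.
    """

    pairs: np.ndarray
    assignment: np.ndarray
    n_folds: int
    seed: int

    def test_pairs(self, fold: int) -> np.ndarray:
        return self.pairs[self.assignment == fold]


@dataclass
class EvaluationReport:
    """Cross-validation results."""

    protocol: str
    fold_aucs: list[float]
    fold_auprs: list[float]
    pooled_auc: float
    pooled_aupr: float
    roc_points: np.ndarray | None = None
    pr_points: np.ndarray | None = None
    per_disease: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    @property
    def mean_fold_auc(self) -> float:
        return float(np.mean(self.fold_aucs)) if self.fold_aucs else float("nan")

    def to_dict(self) -> dict:
        out = {
            "protocol": self.protocol,
            "pooled_auc": self.pooled_auc,
            "pooled_aupr": self.pooled_aupr,
            "mean_fold_auc": self.mean_fold_auc,
            "fold_aucs": self.fold_aucs,
            "fold_auprs": self.fold_auprs,
        }
        if self.per_disease is not None:
            out["per_disease"] = self.per_disease.to_dict(orient="records")
        return out


@dataclass
class RankedCandidates:
    """Per-disease ranking of candidate miRNAs by predicted score."""

    disease: str
    candidates: list[tuple[str, float, bool]]
    top_k: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r + 1, m, s) for r, (m, s, _) in enumerate(self.candidates)],
            columns=["rank", "miRNA", "score"],
        )


def make_folds(
    dataset: AssociationDataset, n_folds: int = 5, seed: int = 0
) -> FoldPlan:
    """Uniformly random seeded partition of the 1-entries into folds."""
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    pairs = dataset.known_pairs()
    if n_folds > len(pairs):
        raise ValueError(
            f"n_folds={n_folds} exceeds the {len(pairs)} known associations"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    assignment = np.empty(len(pairs), dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        assignment[chunk] = f
    return FoldPlan(pairs=pairs, assignment=assignment, n_folds=n_folds, seed=seed)


def _scores_labels(scores, labels):
    if labels is None:
        arr = np.asarray(list(scores), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected (score, label) pairs")
        s, y = arr[:, 0], arr[:, 1]
    else:
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both positive and negative labels are required")
    return s, y


def roc_auc(scores, labels=None) -> tuple[float, np.ndarray]:
    """Trapezoid area under the ROC curve, with tied scores grouped into a
    single threshold step.

    Accepts either an iterable of ``(score, label)`` pairs or two arrays.
    Returns ``(auc, points)`` where points columns are (FPR, TPR).
    """
    s, y = _scores_labels(scores, labels)
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def pr_aupr(scores, labels=None) -> tuple[float, np.ndarray]:
    """Trapezoid area under the precision-recall curve over recall.

    Returns ``(aupr, points)`` where points columns are (recall, precision).
    """
    s, y = _scores_labels(scores, labels)
    precision, recall, _ = precision_recall_curve(y, s)
    rec, prec = recall[::-1], precision[::-1]  # ascending recall
    aupr = float(np.trapezoid(prec, rec))
    return aupr, np.column_stack([rec, prec])


def fold_training_matrix(
    dataset: AssociationDataset, plan: FoldPlan, fold: int
) -> np.ndarray:
    """Training matrix for one fold: the full Y with held-out positives zeroed."""
    Y = dataset.Y.copy()
    test = plan.test_pairs(fold)
    Y[test[:, 0], test[:, 1]] = 0.0
    return Y


def fold_similarities(
    Y_train: np.ndarray,
    dataset: AssociationDataset,
    mesh_table: MeshTable | None,
    fs: SimilarityMatrix | None,
    delta: float = 0.5,
    gamma_prime: float = 1.0,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """(S_m, S_d) integrated similarities computed from a training matrix."""
    S_m = mirna_similarity(Y_train, dataset.mirna_names, fs=fs,
                           gamma_prime=gamma_prime)
    S_d = disease_similarity(Y_train, dataset.disease_names, mesh_table,
                             delta=delta, gamma_prime=gamma_prime)
    return S_m, S_d


def _checksum(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def run_fivefold(
    dataset: AssociationDataset,
    mesh_table: MeshTable | None = None,
    fs: SimilarityMatrix | None = None,
    hyper: Hyperparams | None = None,
    n_folds: int = 5,
    seed: int = 0,
    fold_plan: FoldPlan | None = None,
    delta: float = 0.5,
    gamma_prime: float = 1.0,
) -> EvaluationReport:
    """Global fivefold cross-validation.

    Per fold, held-out positives are zeroed in the training matrix and the
    GIP kernels recomputed from it; the test set is the held-out positives
    against every pair never labelled positive in the full dataset.
    """
    hyper = hyper or Hyperparams()
    plan = fold_plan if fold_plan is not None else make_folds(dataset, n_folds, seed)
    Y = dataset.Y
    neg_i, neg_j = np.nonzero(Y == 0)
    if len(neg_i) == 0:
        raise ValueError("dataset has no negative pairs to score against")

    # The semantic part of S_d and the FS part of S_m do not depend on Y, but
    # integration with the fold GIP kernel happens inside the loop.
    fold_aucs, fold_auprs = [], []
    pooled_scores, pooled_labels = [], []
    sim_checksums = []
    for f in range(plan.n_folds):
        Y_train = fold_training_matrix(dataset, plan, f)
        S_m, S_d = fold_similarities(
            Y_train, dataset, mesh_table, fs, delta=delta, gamma_prime=gamma_prime
        )
        sim_checksums.append(_checksum(S_m.values, S_d.values))
        model = fit(Y_train, S_m.values, S_d.values,
                    hyper.replace(seed=hyper.seed + f))
        ystar = predict(model)
        test = plan.test_pairs(f)
        s = np.concatenate([ystar[test[:, 0], test[:, 1]], ystar[neg_i, neg_j]])
        y = np.concatenate([np.ones(len(test)), np.zeros(len(neg_i))])
        auc, _ = roc_auc(s, y)
        aupr, _ = pr_aupr(s, y)
        fold_aucs.append(auc)
        fold_auprs.append(aupr)
        pooled_scores.append(s)
        pooled_labels.append(y)
        logger.info("fold %d/%d: AUC %.4f AUPR %.4f (%d test positives)",
                    f + 1, plan.n_folds, auc, aupr, len(test))

    s = np.concatenate(pooled_scores)
    y = np.concatenate(pooled_labels)
    pooled_auc, roc_points = roc_auc(s, y)
    pooled_aupr, pr_points = pr_aupr(s, y)
    return EvaluationReport(
        protocol="fivefold",
        fold_aucs=fold_aucs,
        fold_auprs=fold_auprs,
        pooled_auc=pooled_auc,
        pooled_aupr=pooled_aupr,
        roc_points=roc_points,
        pr_points=pr_points,
        extras={
            "fold_plan": plan,
            "similarity_checksums": sim_checksums,
            "pooled_scores": s,
            "pooled_labels": y,
        },
    )


def run_cv_d(
    dataset: AssociationDataset,
    mesh_table: MeshTable | None = None,
    fs: SimilarityMatrix | None = None,
    hyper: Hyperparams | None = None,
    disease_subset: Sequence[str] | None = None,
    delta: float = 0.5,
    gamma_prime: float = 1.0,
) -> EvaluationReport:
    """New-disease cross-validation: zero one disease column, refit, rank.

    Diseases with no known miRNA, or with every miRNA known (no negatives to
    rank against), are skipped with a warning.  The headline number is the
    mean of the per-disease AUCs.
    """
    hyper = hyper or Hyperparams()
    Y = dataset.Y
    if disease_subset is None:
        names = list(dataset.disease_names)
    else:
        names = list(disease_subset)
    records = []
    for name in names:
        j = dataset.disease_index(name)
        col = Y[:, j]
        n_pos = int(col.sum())
        if n_pos == 0:
            logger.warning("CV_d: disease %r has no known miRNA; skipped", name)
            continue
        if n_pos == dataset.n_mirna:
            logger.warning(
                "CV_d: every miRNA is known for disease %r; skipped", name
            )
            continue
        Y_train = Y.copy()
        Y_train[:, j] = 0.0
        S_m, S_d = fold_similarities(
            Y_train, dataset, mesh_table, fs, delta=delta, gamma_prime=gamma_prime
        )
        model = fit(Y_train, S_m.values, S_d.values, hyper)
        scores = predict(model)[:, j]
        auc, _ = roc_auc(scores, col)
        records.append({"disease": dataset.disease_names[j], "auc": auc,
                        "n_pos": n_pos})
        logger.info("CV_d %r: AUC %.4f (%d positives)", name, auc, n_pos)
    if not records:
        raise ValueError("no evaluable disease in CV_d")
    per_disease = pd.DataFrame(records)
    mean_auc = float(per_disease["auc"].mean())
    return EvaluationReport(
        protocol="cv_d",
        fold_aucs=list(per_disease["auc"]),
        fold_auprs=[],
        pooled_auc=mean_auc,
        pooled_aupr=float("nan"),
        per_disease=per_disease,
    )


def sweep_lambda(
    dataset: AssociationDataset,
    mesh_table: MeshTable | None,
    fs: SimilarityMatrix | None,
    grid: Sequence[tuple[float, float]],
    hyper: Hyperparams | None = None,
    n_folds: int = 5,
    seed: int = 0,
    delta: float = 0.5,
    gamma_prime: float = 1.0,
) -> pd.DataFrame:
    """Fivefold AUC/AUPR over a grid of (lambda_m, lambda_d), with a single
    shared fold plan so differences are attributable to the penalties only.
    """
    hyper = hyper or Hyperparams()
    plan = make_folds(dataset, n_folds, seed)
    rows = []
    for lam_m, lam_d in grid:
        report = run_fivefold(
            dataset, mesh_table, fs,
            hyper.replace(lambda_m=lam_m, lambda_d=lam_d),
            fold_plan=plan, delta=delta, gamma_prime=gamma_prime,
        )
        rows.append({
            "lambda_m": lam_m,
            "lambda_d": lam_d,
            "pooled_auc": report.pooled_auc,
            "pooled_aupr": report.pooled_aupr,
            "mean_fold_auc": report.mean_fold_auc,
        })
    return pd.DataFrame(rows)


def rank_candidates(
    model_or_scores,
    dataset: AssociationDataset,
    disease: str,
    top_k: int | None = None,
) -> RankedCandidates:
    """Rank unverified miRNAs for one disease by predicted score.

    miRNAs already known to be associated are excluded; ties are broken by
    miRNA index ascending.  ``top_k`` larger than the candidate list simply
    truncates to what exists.
    """
    if isinstance(model_or_scores, FactorModel):
        ystar = predict(model_or_scores)
    else:
        ystar = np.asarray(model_or_scores, dtype=float)
    if ystar.shape != dataset.Y.shape:
        raise ValueError("score matrix shape does not match dataset")
    j = dataset.disease_index(disease)
    scores = ystar[:, j]
    unknown = np.nonzero(dataset.Y[:, j] == 0)[0]
    order = unknown[np.lexsort((unknown, -scores[unknown]))]
    if top_k is not None:
        order = order[:top_k]
    candidates = [
        (dataset.mirna_names[i], float(scores[i]), False) for i in order
    ]
    return RankedCandidates(
        disease=dataset.disease_names[j], candidates=candidates, top_k=top_k
    )
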