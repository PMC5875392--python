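"""Model validation: stratified tenfold cross-validation of the cascade
and independent-set evaluation of any fitted model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cascade import CascadeModel, build_cascade, build_cascade_fixed_panel, predict_cascade
from .datamodel import CohortLabels, ExpressionMatrix
from .mlr import MlrModel, predict_mlr
from .rbf import RbfConfig
from .stats import (
    ConfusionCounts,
    auc_only,
    classification_metrics,
    confusion_counts,
)

__all__ = ["CvResult", "EvaluationReport", "tenfold_cv", "evaluate"]


@dataclass
class CvResult:
    """Out-of-fold pooled scores and per-fold metrics from k-fold CV."""

    n_folds: int
    fold_assignments: dict[str, int]
    pooled_scores: dict[str, float]
    pooled_auc: float
    per_fold_auc: list[float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_folds": self.n_folds,
                    "fold_assignments": self.fold_assignments,
                    "pooled_scores": self.pooled_scores,
                    "pooled_auc": self.pooled_auc,
                    "per_fold_auc": self.per_fold_auc,
                    "seed": self.seed,
                },
                indent=1,
            )
        )


@dataclass
class EvaluationReport:
    """Headline metrics of one model on one cohort (percent scale)."""

    model_id: str
    cohort_label: str
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    counts: ConfusionCounts

    def to_row(self) -> str:
        return (
            f"{self.model_id}\t{self.cohort_label}\t{self.auc:.4f}\t"
            f"{self.sensitivity:.1f}\t{self.specificity:.1f}\t{self.accuracy:.1f}\t"
            f"{self.counts.tp}\t{self.counts.fp}\t{self.counts.tn}\t{self.counts.fn}"
        )

    @staticmethod
    def header() -> str:
        return (
            "model\tcohort\tauc\tsensitivity_pct\tspecificity_pct\taccuracy_pct"
            "\ttp\tfp\ttn\tfn"
        )


def tenfold_cv(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    panel: list[str],
    seed: int = 0,
    n_folds: int = 10,
    reselect_panel: bool = False,
    candidates: dict[str, float] | None = None,
    epsilon: float = 1e-4,
    rbf_config: RbfConfig | None = None,
) -> CvResult:
    """Stratified k-fold cross-validation of the cascade.

    Per fold, cascade weights are retrained on the other folds with the
    FIXED panel (greedy selection is not re-run unless
    ``reselect_panel=True``, in which case ``candidates`` supplies the
    selection pool); the held-out fold is scored, and one pooled ROC/AUC
    is computed from all out-of-fold scores.
    """
    if not panel and not reselect_panel:
        raise ValueError("panel must be non-empty")
    status = labels.status_for(matrix.sample_ids)
    if min(np.sum(status == 1), np.sum(status == 0)) < n_folds:
        raise ValueError(f"each class needs at least {n_folds} samples")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
    sample_ids = np.asarray(matrix.sample_ids, dtype=object)

    fold_assignments: dict[str, int] = {}
    pooled_scores: dict[str, float] = {}
    per_fold_auc: list[float] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(sample_ids, status)):
        train_ids = list(sample_ids[train_idx])
        test_ids = list(sample_ids[test_idx])
        for s in test_ids:
            fold_assignments[s] = fold
        m_train = matrix.subset_samples(train_ids)
        l_train = labels.subset(train_ids)
        if reselect_panel:
            if not candidates:
                raise ValueError("reselect_panel requires candidates")
            model = build_cascade(
                m_train, l_train, candidates, epsilon=epsilon,
                seed=seed + fold, rbf_config=rbf_config,
            )
        else:
            model = build_cascade_fixed_panel(
                m_train, l_train, panel, seed=seed + fold, rbf_config=rbf_config
            )
        scores, _ = predict_cascade(model, matrix.subset_samples(test_ids))
        for s, v in zip(test_ids, scores):
            pooled_scores[s] = float(v)
        per_fold_auc.append(auc_only(scores, status[test_idx]))

    pooled = np.array([pooled_scores[s] for s in matrix.sample_ids])
    pooled_auc = auc_only(pooled, status)
    return CvResult(
        n_folds=n_folds,
        fold_assignments=fold_assignments,
        pooled_scores=pooled_scores,
        pooled_auc=float(pooled_auc),
        per_fold_auc=[float(a) for a in per_fold_auc],
        seed=int(seed),
    )


def evaluate(
    model: CascadeModel | MlrModel,
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    cohort_label: str = "validation",
    model_id: str | None = None,
) -> EvaluationReport:
    """Score a cohort with a fitted model and report the headline metrics.

    Classes come from the model's frozen decision cutoff; AUC from the
    raw scores.
    """
    if isinstance(model, CascadeModel):
        scores, classes = predict_cascade(model, matrix)
        default_id = "nnc"
    elif isinstance(model, MlrModel):
        scores, classes = predict_mlr(model, matrix)
        default_id = "mlr"
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    status = labels.status_for(matrix.sample_ids)
    counts = confusion_counts(classes, status)
    sens, spec, acc = classification_metrics(counts)
    if np.all(scores == scores[0]):
        auc = 0.5  # constant scorer carries no ranking information
    else:
        auc = auc_only(scores, status)
        auc = max(auc, 1.0 - auc)
    return EvaluationReport(
        model_id=model_id or default_id,
        cohort_label=cohort_label,
        auc=float(auc),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        counts=counts,
    )
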