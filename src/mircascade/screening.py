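"""Stage 1: independent per-feature ROC screening on the training set.

Every feature is scored as a standalone biomarker; candidates must pass
both the AUC and p-value thresholds conjunctively (defaults AUC >= 0.95,
p < 0.0001).  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datamodel import CohortLabels, ExpressionMatrix
from .stats import RocResult, roc_auc

__all__ = ["ScreeningReport", "screen_features", "auc_histogram"]

HISTOGRAM_LO = 0.5
HISTOGRAM_HI = 1.0
HISTOGRAM_WIDTH = 0.01


def auc_histogram(aucs) -> tuple[np.ndarray, np.ndarray]:
    """Counts of AUC values in width-0.01 bins over [0.5, 1].

    Bins are half-open [lo, hi) except the final bin, closed at 1.0.
    Returns (bin_edges, counts).
    """
    aucs = np.asarray(aucs, dtype=float)
    n_bins = int(round((HISTOGRAM_HI - HISTOGRAM_LO) / HISTOGRAM_WIDTH))
    edges = HISTOGRAM_LO + HISTOGRAM_WIDTH * np.arange(n_bins + 1)
    idx = np.minimum(
        np.floor((aucs - HISTOGRAM_LO) / HISTOGRAM_WIDTH).astype(int), n_bins - 1
    )
    counts = np.bincount(idx, minlength=n_bins)
    return edges, counts


@dataclass
class ScreeningReport:
    """Per-feature ROC table, AUC histogram and the passing candidate set."""

    feature_ids: list[str]
    results: dict[str, RocResult]
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray
    candidate_ids: list[str]
    auc_threshold: float
    p_threshold: float

    def candidate_aucs(self) -> dict[str, float]:
        return {f: self.results[f].auc for f in self.candidate_ids}

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(
                "feature_id\tauc\tse\tp_value\tpolarity\tcutoff\t"
                "sensitivity\tspecificity\tcandidate\n"
            )
            for fid in self.feature_ids:
                r = self.results[fid]
                fh.write(
                    f"{fid}\t{r.auc:.6g}\t{r.se:.6g}\t{r.p_value:.6g}\t"
                    f"{r.polarity:+d}\t{r.cutoff:.6g}\t{r.sensitivity:.6g}\t"
                    f"{r.specificity:.6g}\t{int(fid in set(self.candidate_ids))}\n"
                )

    def write_histogram_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("bin_lo\tbin_hi\tcount\n")
            for lo, hi, c in zip(
                self.histogram_edges[:-1], self.histogram_edges[1:], self.histogram_counts
            ):
                fh.write(f"{lo:.2f}\t{hi:.2f}\t{int(c)}\n")

    def write_candidates(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{f}\n" for f in self.candidate_ids))


def screen_features(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    auc_threshold: float = 0.95,
    p_threshold: float = 0.0001,
) -> ScreeningReport:
    """Evaluate every feature independently and select high-AUC candidates.

    A feature is a candidate iff ``auc >= auc_threshold`` AND
    ``p < p_threshold``.  Screening itself is deterministic.
    """
    if not 0.5 <= auc_threshold <= 1.0:
        raise ValueError(f"auc_threshold must be in [0.5, 1], got {auc_threshold}")
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    status = labels.status_for(matrix.sample_ids)
    results: dict[str, RocResult] = {}
    for i, fid in enumerate(matrix.feature_ids):
        try:
            results[fid] = roc_auc(matrix.values[i], status)
        except ValueError as exc:
            raise ValueError(f"feature {fid!r}: {exc}") from exc
    candidates = [
        f
        for f in matrix.feature_ids
        if results[f].auc >= auc_threshold and results[f].p_value < p_threshold
    ]
    edges, counts = auc_histogram([results[f].auc for f in matrix.feature_ids])
    return ScreeningReport(
        feature_ids=list(matrix.feature_ids),
        results=results,
        histogram_edges=edges,
        histogram_counts=counts,
        candidate_ids=candidates,
        auc_threshold=auc_threshold,
        p_threshold=p_threshold,
    )
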