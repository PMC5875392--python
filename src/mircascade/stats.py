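"""Shared statistics: ROC/AUC with significance, Youden cutoff,
classification metrics, Spearman correlation, and the D'Agostino-Pearson
omnibus normality test.

AUC is the Mann-Whitney probability that a random case outscores a random
control (ties count one half).  Down-regulated features are handled by a
polarity flip so the reported AUC is always >= 0.5 with the orientation
recorded.  The AUC standard error follows Hanley & McNeil; the p-value is
a two-sided normal test of AUC = 0.5 using the tie-corrected Mann-Whitney
null variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RocResult",
    "ConfusionCounts",
    "NormalityResult",
    "roc_auc",
    "auc_only",
    "youden_cutoff",
    "classification_metrics",
    "confusion_counts",
    "spearman_rho",
    "dagostino_pearson",
]


@dataclass
class RocResult:
    """Per-feature ROC summary: AUC (>= 0.5), SE, p-value, orientation,
    and Youden-optimal operating point."""

    auc: float
    se: float
    p_value: float
    polarity: int
    cutoff: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not 0.5 <= self.auc <= 1.0 + 1e-12:
            raise ValueError(f"polarity-adjusted AUC must be in [0.5, 1], got {self.auc}")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))


@dataclass
class NormalityResult:
    k2_statistic: float
    p_value: float
    n: int


def _check_two_class(scores: np.ndarray, status: np.ndarray) -> None:
    if scores.shape != status.shape or scores.ndim != 1:
        raise ValueError("scores and status must be equal-length vectors")
    if scores.size == 0:
        raise ValueError("empty input")
    if not (np.any(status == 1) and np.any(status == 0)):
        raise ValueError("both classes must be present")


def auc_only(scores, status) -> float:
    """Raw (un-flipped) Mann-Whitney AUC of cases over controls."""
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    _check_two_class(scores, status)
    n1 = int(np.sum(status == 1))
    n0 = status.size - n1
    ranks = sps.rankdata(scores)  # mid-ranks handle ties -> half credit
    r1 = float(np.sum(ranks[status == 1]))
    u = r1 - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def roc_auc(scores, status) -> RocResult:
    """Full ROC evaluation of a score vector against 0/1 status.

    The AUC equals the pairwise case-over-control count (ties half), flipped
    to >= 0.5 with ``polarity`` recording the orientation.  The cutoff,
    sensitivity and specificity come from :func:`youden_cutoff` on the
    polarity-oriented scores.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    _check_two_class(scores, status)
    n1 = int(np.sum(status == 1))
    n0 = status.size - n1
    n = status.size

    auc_raw = auc_only(scores, status)
    polarity = 1 if auc_raw >= 0.5 else -1
    auc = auc_raw if polarity == 1 else 1.0 - auc_raw

    # Hanley-McNeil standard error at the observed AUC
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc * auc) + (n0 - 1) * (q2 - auc * auc)) / (
        n1 * n0
    )
    se = float(np.sqrt(max(var, 0.0)))

    # two-sided normal test of AUC = 0.5 with tie-corrected null variance
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var0 = (n1 * n0 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    if var0 <= 0:  # all scores tied
        p_value = 1.0
    else:
        u = auc * n1 * n0
        z = (u - n1 * n0 / 2.0) / np.sqrt(var0)
        p_value = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))

    cutoff, sens, spec = youden_cutoff(scores, status, polarity)
    return RocResult(float(auc), se, p_value, polarity, cutoff, sens, spec)


def youden_cutoff(scores, status, polarity: int = 1) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints between adjacent distinct
    polarity-oriented scores, with -inf/+inf sentinels at the extremes;
    a sample is called positive when its oriented score >= cutoff.  Ties in
    J are broken toward the lowest cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    _check_two_class(scores, status)
    if polarity not in (1, -1):
        raise ValueError("polarity must be +1 or -1")
    oriented = scores * polarity

    distinct = np.unique(oriented)
    cuts = np.concatenate(
        ([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf])
    )
    cases = np.sort(oriented[status == 1])
    ctrls = np.sort(oriented[status == 0])
    # positive call is oriented score >= cutoff
    sens = (cases.size - np.searchsorted(cases, cuts, side="left")) / cases.size
    spec = np.searchsorted(ctrls, cuts, side="left") / ctrls.size
    j = sens + spec - 1.0
    # ties in J (within 1e-12) break toward the lowest cutoff
    i = int(np.argmax(j >= j.max() - 1e-12))
    return float(cuts[i]), float(sens[i]), float(spec[i])


def confusion_counts(pred, status) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=int)
    status = np.asarray(status, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (status == 1))),
        fp=int(np.sum((pred == 1) & (status == 0))),
        tn=int(np.sum((pred == 0) & (status == 0))),
        fn=int(np.sum((pred == 0) & (status == 1))),
    )


def classification_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy), each as a percentage."""
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be represented in the counts")
    sens = 100.0 * counts.tp / pos
    spec = 100.0 * counts.tn / neg
    acc = 100.0 * (counts.tp + counts.tn) / (pos + neg)
    return sens, spec, acc


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation is undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def dagostino_pearson(x) -> NormalityResult:
    """D'Agostino-Pearson omnibus test: K2 = Z1(skew)^2 + Z2(kurt)^2,
    referred to chi-square with 2 df."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a vector")
    if x.size < 8:
        raise ValueError(f"need n >= 8 observations, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("normality test is undefined for a constant vector")
    k2, p = sps.normaltest(x)
    return NormalityResult(float(k2), float(p), int(x.size))
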