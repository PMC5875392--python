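"""Stepwise multiple linear regression baseline.

Classic probability-of-F stepwise selection (entry p < 0.05, removal
p > 0.10, SPSS-style defaults): at each step the excluded candidate with
the smallest partial-F p-value enters if below the entry threshold, then
any included feature whose partial-F p-value exceeds the removal
threshold is dropped, iterating to a fixed point.  The fitted model is a
linear probability model — ordinary least squares of the 0/1 status on
the included features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .datamodel import CohortLabels, ExpressionMatrix, NormalizationParams, apply_normalization
from .stats import youden_cutoff

__all__ = ["MlrModel", "fit_stepwise_mlr", "predict_mlr", "save_mlr", "load_mlr"]

MLR_SCHEMA_VERSION = 1


@dataclass
class MlrModel:
    included_features: list[str]
    coefficients: np.ndarray
    intercept: float
    entry_p: float
    removal_p: float
    decision_cutoff: float
    normalization: NormalizationParams | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.included_features),):
            raise ValueError("one coefficient required per included feature")


def _partial_f_p(x_base: np.ndarray, x_new: np.ndarray, y: np.ndarray) -> float:
    """p-value of the partial F test for adding x_new to x_base (both with
    intercept included in x_base)."""
    n = y.size
    q, _ = np.linalg.qr(x_base)
    resid_base = y - q @ (q.T @ y)
    rss_base = float(resid_base @ resid_base)
    x_full = np.column_stack([x_base, x_new])
    qf, rf = np.linalg.qr(x_full)
    if abs(rf[-1, -1]) < 1e-10 * max(1.0, abs(rf[0, 0])):
        return np.nan  # collinear with current model
    resid_full = y - qf @ (qf.T @ y)
    rss_full = float(resid_full @ resid_full)
    df_full = n - x_full.shape[1]
    if df_full <= 0:
        return np.nan
    if rss_full <= 0:
        return 0.0
    f = (rss_base - rss_full) / (rss_full / df_full)
    return float(sps.f.sf(f, 1, df_full))


def fit_stepwise_mlr(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    candidates: list[str],
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    normalization: NormalizationParams | None = None,
) -> MlrModel:
    """Stepwise OLS of the 0/1 status on normalized candidate features.

    Candidates perfectly collinear with the current model are skipped with
    a warning.  The decision cutoff is the Youden cutoff of the fitted
    values, frozen at fit time.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    status = labels.status_for(matrix.sample_ids).astype(float)
    n = status.size
    if n <= len(candidates) + 1:
        raise ValueError("need more observations than candidates + 1")
    cols = {f: matrix.feature_values(f).astype(float) for f in candidates}

    included: list[str] = []
    for _ in range(2 * len(candidates) + 1):  # fixed-point loop guard
        changed = False
        x_base = np.column_stack(
            [np.ones(n)] + [cols[f] for f in included]
        )
        # entry step
        best_p, best_f = np.inf, None
        for f in candidates:
            if f in included:
                continue
            p = _partial_f_p(x_base, cols[f], status)
            if np.isnan(p):
                warnings.warn(
                    f"candidate {f!r} is collinear with the current model; skipped",
                    stacklevel=2,
                )
                continue
            if p < best_p:
                best_p, best_f = p, f
        if best_f is not None and best_p < entry_p:
            included.append(best_f)
            changed = True
        # removal step: drop the worst included feature if above removal_p
        while len(included) > 0:
            x_all = np.column_stack([np.ones(n)] + [cols[f] for f in included])
            worst_p, worst_f = -np.inf, None
            for i, f in enumerate(included):
                others = [g for g in included if g != f]
                x_rest = np.column_stack([np.ones(n)] + [cols[g] for g in others])
                p = _partial_f_p(x_rest, cols[f], status)
                if not np.isnan(p) and p > worst_p:
                    worst_p, worst_f = p, f
            if worst_f is not None and worst_p > removal_p:
                included.remove(worst_f)
                changed = True
            else:
                break
        if not changed:
            break

    x = np.column_stack([np.ones(n)] + [cols[f] for f in included])
    beta, *_ = np.linalg.lstsq(x, status, rcond=None)
    fitted = x @ beta
    if np.all(fitted == fitted[0]):  # intercept-only degenerate model
        cutoff = float(fitted[0])
    else:
        cutoff, _, _ = youden_cutoff(fitted, status.astype(int), polarity=1)
    return MlrModel(
        included_features=included,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        entry_p=float(entry_p),
        removal_p=float(removal_p),
        decision_cutoff=float(cutoff),
        normalization=normalization,
    )


def predict_mlr(
    model: MlrModel, matrix: ExpressionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Linear scores and thresholded classes for a cohort."""
    missing = [f for f in model.included_features if f not in set(matrix.feature_ids)]
    if missing:
        raise KeyError(f"model feature {missing[0]!r} missing from matrix")
    if model.included_features:
        sub = matrix.subset_features(model.included_features)
        if model.normalization is not None:
            sub = apply_normalization(sub, model.normalization)
        scores = model.intercept + model.coefficients @ sub.values
    else:
        scores = np.full(matrix.n_samples, model.intercept)
    classes = (scores >= model.decision_cutoff).astype(int)
    return scores, classes


def save_mlr(model: MlrModel, path: str | Path) -> None:
    doc = {
        "schema_version": MLR_SCHEMA_VERSION,
        "included_features": model.included_features,
        "coefficients": model.coefficients.tolist(),
        "intercept": model.intercept,
        "entry_p": model.entry_p,
        "removal_p": model.removal_p,
        "decision_cutoff": model.decision_cutoff,
        "normalization": (
            model.normalization.to_dict() if model.normalization is not None else None
        ),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_mlr(path: str | Path) -> MlrModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != MLR_SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema version")
    return MlrModel(
        included_features=list(doc["included_features"]),
        coefficients=np.array(doc["coefficients"], dtype=float),
        intercept=float(doc["intercept"]),
        entry_p=float(doc["entry_p"]),
        removal_p=float(doc["removal_p"]),
        decision_cutoff=float(doc["decision_cutoff"]),
        normalization=(
            NormalizationParams.from_dict(doc["normalization"])
            if doc["normalization"] is not None
            else None
        ),
    )
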