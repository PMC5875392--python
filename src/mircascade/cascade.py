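"""Neural-network cascade: greedy layer-wise panel construction.

Layer 1 is a single-input RBF unit on the highest-AUC candidate.  Every
later layer pairs the current cascade output with one remaining
candidate's cached single-input unit output in a freshly trained
two-input combiner; the candidate giving the maximum AUC on the full
modeling set is accepted iff the gain exceeds ``epsilon``, otherwise the
build terminates.  A cascade over k panel members therefore has exactly
k single-input units and k-1 combiners.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seeding import derive_seed
from .datamodel import CohortLabels, ExpressionMatrix, NormalizationParams, apply_normalization
from .rbf import RbfConfig, RbfUnit, TrainingReport, predict_rbf, train_rbf
from .stats import auc_only, youden_cutoff

__all__ = [
    "CascadeModel",
    "build_cascade",
    "build_cascade_fixed_panel",
    "predict_cascade",
    "save_cascade",
    "load_cascade",
]

SCHEMA_VERSION = 1


@dataclass
class CascadeModel:
    """Ordered cascade of RBF units over a biomarker panel."""

    panel: list[str]
    feature_units: list[RbfUnit]
    combiner_units: list[RbfUnit]
    layer_auc_trace: list[float]
    epsilon: float
    decision_cutoff: float
    seed: int
    normalization: NormalizationParams | None = None
    training_reports: list[TrainingReport] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.feature_units) != len(self.panel):
            raise ValueError("one single-input unit required per panel member")
        if len(self.combiner_units) != max(len(self.panel) - 1, 0):
            raise ValueError("a k-member cascade must have k-1 combiners")
        if len(self.layer_auc_trace) != len(self.panel):
            raise ValueError("one AUC trace entry required per layer")


def _forward(model: CascadeModel, inputs: np.ndarray) -> np.ndarray:
    """Forward pass given normalized panel inputs (n_panel, n_samples)."""
    out = predict_rbf(model.feature_units[0], inputs[0][:, None])
    for k in range(1, len(model.panel)):
        feat_out = predict_rbf(model.feature_units[k], inputs[k][:, None])
        out = predict_rbf(
            model.combiner_units[k - 1], np.column_stack([out, feat_out])
        )
    return out


def build_cascade(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    candidates: dict[str, float],
    epsilon: float = 1e-4,
    seed: int = 0,
    normalization: NormalizationParams | None = None,
    rbf_config: RbfConfig | None = None,
) -> CascadeModel:
    """Greedy cascade construction over retained candidates.

    ``matrix`` must already be normalized to [0, 1]; ``candidates`` maps
    feature ID -> screening AUC (sets the entry/tie-break order:
    descending AUC, then lexicographic ID).  AUC gain is measured on the
    full modeling set.  ``normalization`` is stored on the model so that
    prediction on raw cohorts can re-apply it.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    status = labels.status_for(matrix.sample_ids)
    order = sorted(candidates, key=lambda f: (-candidates[f], f))

    # cache one single-input unit per candidate, trained once
    unit_cache: dict[str, RbfUnit] = {}
    report_cache: dict[str, TrainingReport] = {}
    unit_out: dict[str, np.ndarray] = {}
    for fid in order:
        x = matrix.feature_values(fid)[:, None]
        unit, report = train_rbf(
            x, status, derive_seed(seed, "feature_unit", fid), config=rbf_config
        )
        unit.input_feature_refs = [fid]
        unit_cache[fid] = unit
        report_cache[fid] = report
        unit_out[fid] = predict_rbf(unit, x)

    first = order[0]
    panel = [first]
    feature_units = [unit_cache[first]]
    combiners: list[RbfUnit] = []
    reports = [report_cache[first]]
    current = unit_out[first]
    trace = [auc_only(current, status)]
    remaining = [f for f in order if f != first]

    layer = 2
    while remaining:
        best: tuple[float, str, RbfUnit, TrainingReport, np.ndarray] | None = None
        for fid in remaining:
            inputs = np.column_stack([current, unit_out[fid]])
            comb, rep = train_rbf(
                inputs,
                status,
                derive_seed(seed, "combiner", layer, fid),
                config=rbf_config,
            )
            comb.input_feature_refs = ["cascade_output", fid]
            auc = auc_only(predict_rbf(comb, inputs), status)
            if best is None or auc > best[0]:
                best = (auc, fid, comb, rep, predict_rbf(comb, inputs))
        assert best is not None
        if best[0] - trace[-1] <= epsilon:
            break
        trace.append(best[0])
        panel.append(best[1])
        feature_units.append(unit_cache[best[1]])
        combiners.append(best[2])
        reports.append(best[3])
        current = best[4]
        remaining.remove(best[1])
        layer += 1

    cutoff, _, _ = youden_cutoff(current, status, polarity=1)
    return CascadeModel(
        panel=panel,
        feature_units=feature_units,
        combiner_units=combiners,
        layer_auc_trace=trace,
        epsilon=float(epsilon),
        decision_cutoff=float(cutoff),
        seed=int(seed),
        normalization=normalization,
        training_reports=reports,
    )


def build_cascade_fixed_panel(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    panel: list[str],
    seed: int = 0,
    normalization: NormalizationParams | None = None,
    rbf_config: RbfConfig | None = None,
) -> CascadeModel:
    """Retrain cascade weights for an already-selected panel (no greedy
    search; used by cross-validation and structural tests)."""
    if not panel:
        raise ValueError("panel must be non-empty")
    status = labels.status_for(matrix.sample_ids)
    feature_units: list[RbfUnit] = []
    combiners: list[RbfUnit] = []
    reports: list[TrainingReport] = []
    trace: list[float] = []
    current: np.ndarray | None = None
    for k, fid in enumerate(panel):
        x = matrix.feature_values(fid)[:, None]
        unit, rep = train_rbf(
            x, status, derive_seed(seed, "feature_unit", fid), config=rbf_config
        )
        unit.input_feature_refs = [fid]
        feature_units.append(unit)
        reports.append(rep)
        feat_out = predict_rbf(unit, x)
        if current is None:
            current = feat_out
        else:
            inputs = np.column_stack([current, feat_out])
            comb, crep = train_rbf(
                inputs,
                status,
                derive_seed(seed, "combiner", k + 1, fid),
                config=rbf_config,
            )
            comb.input_feature_refs = ["cascade_output", fid]
            combiners.append(comb)
            reports.append(crep)
            current = predict_rbf(comb, inputs)
        trace.append(auc_only(current, status))
    cutoff, _, _ = youden_cutoff(current, status, polarity=1)
    return CascadeModel(
        panel=list(panel),
        feature_units=feature_units,
        combiner_units=combiners,
        layer_auc_trace=trace,
        epsilon=0.0,
        decision_cutoff=float(cutoff),
        seed=int(seed),
        normalization=normalization,
        training_reports=reports,
    )


def predict_cascade(
    model: CascadeModel, matrix: ExpressionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Score a cohort with a trained cascade.

    If the model carries normalization params the inputs are rescaled
    (and clipped) with them first; otherwise the matrix is assumed
    normalized.  Returns (scores, classes) with
    ``classes = scores >= decision_cutoff``.
    """
    missing = [f for f in model.panel if f not in set(matrix.feature_ids)]
    if missing:
        raise KeyError(f"panel feature {missing[0]!r} missing from matrix")
    sub = matrix.subset_features(model.panel)
    if model.normalization is not None:
        sub = apply_normalization(sub, model.normalization)
    scores = _forward(model, sub.values)
    classes = (scores >= model.decision_cutoff).astype(int)
    return scores, classes


def save_cascade(model: CascadeModel, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "panel": model.panel,
        "feature_units": [u.to_dict() for u in model.feature_units],
        "combiner_units": [u.to_dict() for u in model.combiner_units],
        "layer_auc_trace": model.layer_auc_trace,
        "epsilon": model.epsilon,
        "decision_cutoff": model.decision_cutoff,
        "seed": model.seed,
        "normalization": (
            model.normalization.to_dict() if model.normalization is not None else None
        ),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_cascade(path: str | Path) -> CascadeModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid cascade model file: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unsupported schema version {doc.get('schema_version')!r}"
            if isinstance(doc, dict)
            else f"{path}: not a cascade model document"
        )
    return CascadeModel(
        panel=list(doc["panel"]),
        feature_units=[RbfUnit.from_dict(d) for d in doc["feature_units"]],
        combiner_units=[RbfUnit.from_dict(d) for d in doc["combiner_units"]],
        layer_auc_trace=[float(a) for a in doc["layer_auc_trace"]],
        epsilon=float(doc["epsilon"]),
        decision_cutoff=float(doc["decision_cutoff"]),
        seed=int(doc["seed"]),
        normalization=(
            NormalizationParams.from_dict(doc["normalization"])
            if doc["normalization"] is not None
            else None
        ),
    )
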