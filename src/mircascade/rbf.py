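"""Single radial-basis-function network unit with fixed n-11-1 layout
(n = 1 or 2 inputs, 11 Gaussian hidden units, 1 linear output).

Training recipe: hidden centers by seeded k-means on the training subset,
widths as the mean distance to each center's 2 nearest neighbours
(floored), and a ridge-regularized least-squares output layer.  An
internal stratified 2:1:1 hold-out (training / verification / testing)
provides restart selection and the R_Tr / R_Ve / R_Te report; the testing
subset is never used for any selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from ._seeding import derive_seed
from .datamodel import CohortLabels, round_half_up

__all__ = [
    "RbfUnit",
    "TrainingReport",
    "RbfConfig",
    "holdout_split",
    "train_rbf",
    "predict_rbf",
]

N_HIDDEN = 11
WIDTH_NEIGHBORS = 2
WIDTH_FLOOR = 1e-3
RIDGE_LAMBDA = 1e-6


@dataclass
class RbfConfig:
    """Training constants, config-exposed; defaults follow the n-11-1 recipe."""

    n_hidden: int = N_HIDDEN
    width_neighbors: int = WIDTH_NEIGHBORS
    width_floor: float = WIDTH_FLOOR
    ridge_lambda: float = RIDGE_LAMBDA
    restarts: int = 5


@dataclass
class RbfUnit:
    """A trained (or hand-built) RBF unit.

    ``centers`` has shape (k, n_inputs); ``widths`` and ``weights`` have
    length k; prediction is ``bias + sum_j w_j exp(-||x - c_j||^2 / (2 s_j^2))``.
    """

    n_inputs: int
    centers: np.ndarray
    widths: np.ndarray
    weights: np.ndarray
    bias: float
    input_feature_refs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_inputs not in (1, 2):
            raise ValueError("n_inputs must be 1 or 2")
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.asarray(self.widths, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.centers.shape[1] != self.n_inputs:
            raise ValueError("center dimensionality must match n_inputs")
        k = self.centers.shape[0]
        if self.widths.shape != (k,) or self.weights.shape != (k,):
            raise ValueError("widths and weights must have one entry per center")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be positive")

    def to_dict(self) -> dict:
        return {
            "n_inputs": self.n_inputs,
            "centers": self.centers.tolist(),
            "widths": self.widths.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "input_feature_refs": list(self.input_feature_refs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RbfUnit":
        return cls(
            n_inputs=int(d["n_inputs"]),
            centers=np.array(d["centers"], dtype=float),
            widths=np.array(d["widths"], dtype=float),
            weights=np.array(d["weights"], dtype=float),
            bias=float(d["bias"]),
            input_feature_refs=list(d.get("input_feature_refs", [])),
        )


@dataclass
class TrainingReport:
    """Pearson correlations of unit output with the target on the three
    internal subsets, plus their sizes and the training seed."""

    r_tr: float
    r_ve: float
    r_te: float
    subset_sizes: tuple[int, int, int]
    seed: int


def holdout_split(
    ids: Sequence[str], labels: CohortLabels, seed: int
) -> tuple[list[str], list[str], list[str]]:
    """Stratified 2:1:1 partition into (training, verification, testing).

    Per class: training gets round(n/2), verification round(n/4), testing
    the remainder; membership is a seeded shuffle.
    """
    ids = list(ids)
    if len(ids) < 8:
        raise ValueError("need at least 8 samples for a 2:1:1 hold-out")
    status = labels.status_for(ids)
    rng = np.random.default_rng(seed)
    parts: tuple[list[str], list[str], list[str]] = ([], [], [])
    arr = np.asarray(ids, dtype=object)
    for cls in (1, 0):
        cls_ids = arr[status == cls]
        n = len(cls_ids)
        # each class must put at least 2 samples in every subset
        if n < 8:
            raise ValueError(f"class {cls} too small ({n}) to populate all subsets")
        n_tr = round_half_up(n / 2.0)
        n_ve = round_half_up(n / 4.0)
        n_te = n - n_tr - n_ve
        perm = rng.permutation(n)
        parts[0].extend(cls_ids[perm[:n_tr]])
        parts[1].extend(cls_ids[perm[n_tr : n_tr + n_ve]])
        parts[2].extend(cls_ids[perm[n_tr + n_ve :]])
    return parts


def _gaussian_design(x: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    d2 = np.sum((x[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    return np.exp(-d2 / (2.0 * widths[None, :] ** 2))


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _fit_once(
    x_tr: np.ndarray, y_tr: np.ndarray, n_inputs: int, seed: int, config: RbfConfig
) -> RbfUnit:
    distinct = np.unique(x_tr, axis=0)
    if distinct.shape[0] < 2:
        raise ValueError("fewer than 2 distinct training points")
    k = config.n_hidden
    if distinct.shape[0] < k:
        k = distinct.shape[0]
        warnings.warn(
            f"only {k} distinct training points; reducing hidden units from "
            f"{config.n_hidden} to {k}",
            stacklevel=3,
        )
    km = KMeans(n_clusters=k, n_init=1, random_state=seed % (2**32)).fit(x_tr)
    centers = km.cluster_centers_

    if k == 1:
        widths = np.array([1.0])
    else:
        dists = np.sqrt(
            np.sum((centers[:, None, :] - centers[None, :, :]) ** 2, axis=2)
        )
        np.fill_diagonal(dists, np.inf)
        m = min(config.width_neighbors, k - 1)
        widths = np.sort(dists, axis=1)[:, :m].mean(axis=1)
    widths = np.maximum(widths, config.width_floor)

    phi = _gaussian_design(x_tr, centers, widths)
    design = np.hstack([np.ones((phi.shape[0], 1)), phi])
    reg = config.ridge_lambda * np.eye(design.shape[1])
    reg[0, 0] = 0.0  # intercept unpenalized
    beta = np.linalg.solve(design.T @ design + reg, design.T @ y_tr)
    return RbfUnit(
        n_inputs=n_inputs,
        centers=centers,
        widths=widths,
        weights=beta[1:],
        bias=float(beta[0]),
    )


def train_rbf(
    inputs: np.ndarray,
    targets: np.ndarray,
    seed: int,
    restarts: int | None = None,
    config: RbfConfig | None = None,
) -> tuple[RbfUnit, TrainingReport]:
    """Train an n-11-1 RBF unit with internal 2:1:1 hold-out and restarts.

    ``inputs`` is (n_obs, n_inputs) in [0, 1]; ``targets`` the 0/1 status.
    Each restart re-seeds k-means; the restart with the highest
    verification-subset correlation is kept.
    """
    config = config or RbfConfig()
    if restarts is not None:
        config = RbfConfig(
            config.n_hidden,
            config.width_neighbors,
            config.width_floor,
            config.ridge_lambda,
            restarts,
        )
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim == 1:
        inputs = inputs[:, None]
    targets = np.asarray(targets, dtype=float)
    n_obs, n_inputs = inputs.shape
    if n_inputs not in (1, 2):
        raise ValueError("n_inputs must be 1 or 2")
    if targets.shape != (n_obs,):
        raise ValueError("targets must match inputs row count")

    ids = [str(i) for i in range(n_obs)]
    labels = CohortLabels(ids, targets.astype(int))
    tr, ve, te = holdout_split(ids, labels, derive_seed(seed, "holdout"))
    idx = {s: i for i, s in enumerate(ids)}
    i_tr = np.array([idx[s] for s in tr])
    i_ve = np.array([idx[s] for s in ve])
    i_te = np.array([idx[s] for s in te])

    best: tuple[float, RbfUnit] | None = None
    for r in range(config.restarts):
        unit = _fit_once(
            inputs[i_tr], targets[i_tr], n_inputs, derive_seed(seed, "restart", r), config
        )
        r_ve = _safe_corr(predict_rbf(unit, inputs[i_ve]), targets[i_ve])
        if best is None or r_ve > best[0]:
            best = (r_ve, unit)
    assert best is not None
    unit = best[1]
    report = TrainingReport(
        r_tr=_safe_corr(predict_rbf(unit, inputs[i_tr]), targets[i_tr]),
        r_ve=best[0],
        r_te=_safe_corr(predict_rbf(unit, inputs[i_te]), targets[i_te]),
        subset_sizes=(len(i_tr), len(i_ve), len(i_te)),
        seed=int(seed),
    )
    return unit, report


def predict_rbf(unit: RbfUnit, inputs: np.ndarray) -> np.ndarray:
    """Forward pass: ``y_i = bias + sum_j w_j exp(-||x_i - c_j||^2 / (2 s_j^2))``.

    Outputs are raw reals (no clamping); thresholding happens only in
    evaluation.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim == 1:
        inputs = inputs[:, None]
    if inputs.shape[1] != unit.n_inputs:
        raise ValueError(
            f"input dimensionality {inputs.shape[1]} != unit n_inputs {unit.n_inputs}"
        )
    phi = _gaussian_design(inputs, unit.centers, unit.widths)
    return unit.bias + phi @ unit.weights
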