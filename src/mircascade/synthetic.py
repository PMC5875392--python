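"""Synthetic two-class expression cohort generator.

Samples a latent multivariate normal per participant (Gaussian copula):
features inside a collinear block share a latent factor, so rank
correlation survives any marginal transform; case samples' planted-marker
latents are shifted by ``delta = sqrt(2) * Phi^-1(target_auc)``, which
makes the theoretical AUC of the marker exactly its target under the
unit-variance latent model.  Margins default to lognormal so the
simulated intensities fail normality testing, like the arrays the
pipeline is designed for.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .datamodel import CohortLabels, ExpressionMatrix, write_expression_matrix, write_labels

__all__ = [
    "SyntheticSpec",
    "GroundTruthManifest",
    "shift_for_auc",
    "generate_cohort",
    "write_fixture",
    "paper_shaped_spec",
]

DEFAULT_BLOCK_CORRELATION = 0.9


@dataclass
class SyntheticSpec:
    """Ground-truth design of a simulated cohort.

    ``planted_markers`` maps feature ID -> target AUC in (0.5, 1);
    ``collinear_blocks`` lists disjoint groups of feature IDs sharing a
    latent factor with pairwise latent correlation
    ``block_correlation``.  ``margin`` is ``("lognormal", sigma)`` or
    ``("normal",)``.
    """

    n_cases: int
    n_controls: int
    n_features: int
    planted_markers: dict[str, float] = field(default_factory=dict)
    collinear_blocks: list[list[str]] = field(default_factory=list)
    block_correlation: float = DEFAULT_BLOCK_CORRELATION
    margin: tuple = ("lognormal", 1.0)
    seed: int = 0
    feature_prefix: str = "miR-sim-"
    # Two latently independent markers shifted by delta in the case class
    # acquire pooled-cohort correlation delta_i*delta_j*p*(1-p) /
    # sqrt(...) from the shift alone (~0.59 at AUC 0.97, 1/3 cases) — enough
    # to cross the collinearity threshold.  When True, distinct marker
    # groups are planted with negative within-class latent correlation
    # (capped to keep the covariance PSD) so "non-collinear" planted
    # markers really are non-collinear under the pipeline's pooled metric.
    decorrelate_markers: bool = True
    marker_within_class_rho: float = -0.45

    def feature_ids(self) -> list[str]:
        return [f"{self.feature_prefix}{i:04d}" for i in range(self.n_features)]

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1 or self.n_features < 1:
            raise ValueError("cohort dimensions must be positive")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must be in [0, 1)")
        ids = set(self.feature_ids())
        for fid, auc in self.planted_markers.items():
            if fid not in ids:
                raise ValueError(f"planted marker {fid!r} outside the feature set")
            if not 0.5 < auc < 1.0:
                raise ValueError(f"target AUC for {fid!r} must be in (0.5, 1)")
        seen: set[str] = set()
        for block in self.collinear_blocks:
            for fid in block:
                if fid not in ids:
                    raise ValueError(f"block member {fid!r} outside the feature set")
                if fid in seen:
                    raise ValueError(f"feature {fid!r} appears in more than one block")
                seen.add(fid)
        if self.margin[0] not in ("lognormal", "normal"):
            raise ValueError(f"unknown margin {self.margin[0]!r}")


@dataclass
class GroundTruthManifest:
    """Per-feature theoretical AUC and latent design of a generated cohort."""

    theoretical_auc: dict[str, float]
    delta: dict[str, float]
    blocks: list[list[str]]
    seed: int
    margin: tuple

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "theoretical_auc": self.theoretical_auc,
                    "delta": self.delta,
                    "blocks": self.blocks,
                    "seed": self.seed,
                    "margin": list(self.margin),
                    "note": "lognormal margins are a modeling stand-in for "
                    "non-Gaussian array intensities",
                },
                indent=1,
            )
        )

    def planted_ids(self) -> list[str]:
        return [f for f, d in self.delta.items() if d > 0]


def shift_for_auc(target_auc: float) -> float:
    """Latent mean shift giving ``target_auc`` between unit-variance
    normal classes: ``delta = sqrt(2) * Phi^-1(target_auc)``."""
    if not 0.5 < target_auc < 1.0:
        raise ValueError(f"target_auc must be strictly inside (0.5, 1), got {target_auc}")
    return math.sqrt(2.0) * float(sps.norm.ppf(target_auc))


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, CohortLabels, GroundTruthManifest]:
    """Draw a seeded cohort from the latent Gaussian-copula model.

    Controls come first in the sample order, then cases; labels pair the
    matrix.  Same seed -> identical cohort bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    feature_ids = spec.feature_ids()
    n = spec.n_controls + spec.n_cases
    status = np.concatenate(
        [np.zeros(spec.n_controls, dtype=int), np.ones(spec.n_cases, dtype=int)]
    )
    sample_ids = [f"ctrl-{i:05d}" for i in range(spec.n_controls)] + [
        f"case-{i:05d}" for i in range(spec.n_cases)
    ]

    # latent draws: iid noise for null features; informative features
    # (anything in a block or planted) get a joint covariance — 0.9-style
    # within-block correlation, optional negative cross-group correlation
    # to offset class-shift-induced pooled correlation.
    latent = rng.standard_normal((spec.n_features, n))
    index = {f: i for i, f in enumerate(feature_ids)}
    delta = {f: 0.0 for f in feature_ids}
    for fid, auc in spec.planted_markers.items():
        delta[fid] = shift_for_auc(auc)

    in_block = {f for b in spec.collinear_blocks for f in b}
    informative = [f for f in feature_ids if f in in_block or delta[f] > 0]
    if informative:
        group_of: dict[str, int] = {}
        for g, block in enumerate(spec.collinear_blocks):
            for fid in block:
                group_of[fid] = g
        next_group = len(spec.collinear_blocks)
        for fid in informative:
            if fid not in group_of:
                group_of[fid] = next_group
                next_group += 1
        m = len(informative)
        cov = np.eye(m)
        n_shifted_groups = len({group_of[f] for f in informative if delta[f] > 0})
        cross = (
            spec.marker_within_class_rho
            if spec.decorrelate_markers and n_shifted_groups >= 2
            else 0.0
        )
        for a in range(m):
            for b in range(a + 1, m):
                fa, fb = informative[a], informative[b]
                if group_of[fa] == group_of[fb]:
                    cov[a, b] = cov[b, a] = spec.block_correlation
                elif delta[fa] > 0 and delta[fb] > 0:
                    cov[a, b] = cov[b, a] = cross
        # shrink the negative cross-correlation toward 0 until PSD
        while np.linalg.eigvalsh(cov).min() < 1e-6:
            cross *= 0.9
            for a in range(m):
                for b in range(a + 1, m):
                    fa, fb = informative[a], informative[b]
                    if (
                        group_of[fa] != group_of[fb]
                        and delta[fa] > 0
                        and delta[fb] > 0
                    ):
                        cov[a, b] = cov[b, a] = cross
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((m, n))
        rows = [index[f] for f in informative]
        latent[rows, :] = chol @ z

    for fid in feature_ids:
        if delta[fid] > 0:
            latent[index[fid], status == 1] += delta[fid]

    if spec.margin[0] == "lognormal":
        sigma = float(spec.margin[1]) if len(spec.margin) > 1 else 1.0
        values = np.exp(sigma * latent)
    else:
        values = latent

    matrix = ExpressionMatrix(feature_ids, sample_ids, values)
    labels = CohortLabels(sample_ids, status)
    manifest = GroundTruthManifest(
        theoretical_auc={
            f: float(sps.norm.cdf(delta[f] / math.sqrt(2.0))) for f in feature_ids
        },
        delta=delta,
        blocks=[list(b) for b in spec.collinear_blocks],
        seed=spec.seed,
        margin=spec.margin,
    )
    return matrix, labels, manifest


def write_fixture(spec: SyntheticSpec, directory: str | Path) -> dict[str, Path]:
    """Generate a cohort and write matrix.tsv / labels.tsv / manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix, labels, manifest = generate_cohort(spec)
    paths = {
        "matrix": directory / "matrix.tsv",
        "labels": directory / "labels.tsv",
        "manifest": directory / "manifest.json",
    }
    write_expression_matrix(matrix, paths["matrix"])
    write_labels(labels, paths["labels"])
    manifest.to_json(paths["manifest"])
    return paths


def paper_shaped_spec(seed: int = 0, scale: float = 1.0) -> SyntheticSpec:
    """Preset emulating the reference cohort shape: 1,288 cases / 2,686
    controls x 2,540 features, 8 planted non-collinear markers with AUC
    targets spread over [0.96, 0.99], each with one collinear duplicate.

    ``scale`` shrinks every dimension proportionally for fast smoke runs.
    """
    n_cases = max(int(round(1288 * scale)), 8)
    n_controls = max(int(round(2686 * scale)), 8)
    n_features = max(int(round(2540 * scale)), 24)
    marker_targets = np.linspace(0.96, 0.99, 8)
    planted: dict[str, float] = {}
    blocks: list[list[str]] = []
    prefix = "miR-sim-"
    for i, t in enumerate(marker_targets):
        marker = f"{prefix}{i:04d}"
        dup = f"{prefix}{i + 8:04d}"
        planted[marker] = float(t)
        planted[dup] = float(t) - 0.005  # duplicate slightly weaker
        blocks.append([marker, dup])
    return SyntheticSpec(
        n_cases=n_cases,
        n_controls=n_controls,
        n_features=n_features,
        planted_markers=planted,
        collinear_blocks=blocks,
        seed=seed,
        feature_prefix=prefix,
    )
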