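"""Core data types and file I/O for expression cohorts.

Provides the feature-by-sample expression matrix, binary cohort labels,
stratified train/validation splitting and per-feature 0-1 normalization
fitted on the training partition only.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CohortLabels",
    "SplitAssignment",
    "NormalizationParams",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "stratified_split",
    "round_half_up",
    "fit_normalization",
    "apply_normalization",
]

SERIES_MATRIX_BEGIN = "!series_matrix_table_begin"
SERIES_MATRIX_END = "!series_matrix_table_end"


def _find_duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass
class ExpressionMatrix:
    """Feature-by-sample matrix of normalized expression values.

    ``values`` has shape ``(n_features, n_samples)``; all entries must be
    finite, and feature/sample identifiers must be unique.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = list(map(str, self.feature_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {kind} ID(s): {', '.join(dups)}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``sample_ids`` (in that order)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            cols = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, cols],
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        rows = [self.feature_index(f) for f in feature_ids]
        return ExpressionMatrix(
            feature_ids=list(feature_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
        )

    def feature_values(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_index(feature_id), :]


@dataclass
class CohortLabels:
    """Binary disease-status labels (0 = control, 1 = case) per sample."""

    sample_ids: list[str]
    status: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.status = np.asarray(self.status, dtype=int)
        if self.status.ndim != 1 or len(self.status) != len(self.sample_ids):
            raise ValueError("status must be a vector matching sample_ids")
        dups = _find_duplicates(self.sample_ids)
        if dups:
            raise ValueError(f"duplicate sample ID(s): {', '.join(dups)}")
        bad = set(np.unique(self.status)) - {0, 1}
        if bad:
            raise ValueError(f"status values must be 0 or 1, got {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.status == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.status == 0))

    def status_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Status vector aligned to ``sample_ids``."""
        lookup = dict(zip(self.sample_ids, self.status))
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} has no label") from None

    def subset(self, sample_ids: Sequence[str]) -> "CohortLabels":
        return CohortLabels(list(sample_ids), self.status_for(sample_ids))


@dataclass
class SplitAssignment:
    """Seeded stratified partition of a cohort into training and validation."""

    train_ids: list[str]
    validation_ids: list[str]
    ratio: tuple[int, int]
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"train/validation overlap: {sorted(overlap)[:3]}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_ids": self.train_ids,
                    "validation_ids": self.validation_ids,
                    "ratio": list(self.ratio),
                    "seed": self.seed,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitAssignment":
        d = json.loads(Path(path).read_text())
        return cls(d["train_ids"], d["validation_ids"], tuple(d["ratio"]), d["seed"])


@dataclass
class NormalizationParams:
    """Per-feature min/max fitted on the training partition."""

    feature_ids: list[str]
    minima: np.ndarray
    maxima: np.ndarray

    def __post_init__(self) -> None:
        self.minima = np.asarray(self.minima, dtype=float)
        self.maxima = np.asarray(self.maxima, dtype=float)
        if not np.all(self.maxima > self.minima):
            i = int(np.argmax(~(self.maxima > self.minima)))
            raise ValueError(
                f"feature {self.feature_ids[i]!r} has max <= min "
                f"({self.maxima[i]} <= {self.minima[i]})"
            )

    def to_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "minima": self.minima.tolist(),
            "maxima": self.maxima.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(list(d["feature_ids"]), d["minima"], d["maxima"])


def _parse_table(lines: list[str], path: str) -> ExpressionMatrix:
    if not lines:
        raise ValueError(f"{path}: no data table found")
    text = "\n".join(lines)
    df = pd.read_csv(io.StringIO(text), sep="\t", header=0, dtype=str)
    # strip GEO-style quoting from every cell and identifier
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    sample_ids = list(df.columns[1:])
    feature_col = df.iloc[:, 0].astype(str).str.strip().str.strip('"')
    feature_ids = feature_col.tolist()
    for kind, ids in (("feature", feature_ids), ("sample", sample_ids)):
        dups = _find_duplicates(ids)
        if dups:
            raise ValueError(f"{path}: duplicate {kind} ID(s): {', '.join(dups)}")
    raw = df.iloc[:, 1:].map(lambda s: str(s).strip().strip('"'))
    values = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        col = raw.iloc[:, j].to_numpy()
        for i, cell in enumerate(col):
            try:
                v = float(cell)  # correctly-rounded parse, bit-exact round trip
            except ValueError:
                v = np.nan
            if not np.isfinite(v):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at feature "
                    f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
                )
            values[i, j] = v
    return ExpressionMatrix(feature_ids, sample_ids, values)


def read_expression_matrix(
    path: str | Path, format: str = "plain_tsv"
) -> ExpressionMatrix:
    """Read a feature-by-sample TSV expression matrix.

    ``format`` is ``plain_tsv`` (header row of sample IDs, first column of
    feature IDs) or ``series_matrix_tsv`` (same table wrapped between
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers;
    all ``!``-prefixed metadata lines are ignored).
    """
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    if format == "plain_tsv":
        lines = [ln for ln in raw_lines if ln.strip()]
    elif format == "series_matrix_tsv":
        lines = []
        inside = False
        for ln in raw_lines:
            stripped = ln.strip()
            if stripped == SERIES_MATRIX_BEGIN:
                inside = True
                continue
            if stripped == SERIES_MATRIX_END:
                inside = False
                continue
            if inside and stripped and not stripped.startswith("!"):
                lines.append(ln)
        if not lines:
            raise ValueError(
                f"{path}: no {SERIES_MATRIX_BEGIN}/{SERIES_MATRIX_END} table found"
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    return _parse_table(lines, str(path))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as plain TSV; round-trips bit-exactly via repr floats."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, fid in enumerate(matrix.feature_ids):
            row = "\t".join(repr(float(v)) for v in matrix.values[i])
            fh.write(f"{fid}\t{row}\n")


def read_labels(path: str | Path) -> CohortLabels:
    """Read a two-column TSV of (sample_id, status) with optional header."""
    path = Path(path)
    sample_ids: list[str] = []
    status: list[int] = []
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        sid, st = parts[0].strip().strip('"'), parts[1].strip().strip('"')
        if lineno == 1 and st.lower() in {"status", "label", "class"}:
            continue
        if st not in {"0", "1"}:
            raise ValueError(f"{path}:{lineno}: status must be 0 or 1, got {st!r}")
        sample_ids.append(sid)
        status.append(int(st))
    return CohortLabels(sample_ids, np.array(status, dtype=int))


def write_labels(labels: CohortLabels, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tstatus\n")
        for sid, st in zip(labels.sample_ids, labels.status):
            fh.write(f"{sid}\t{int(st)}\n")


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves rounded up."""
    return int(np.floor(x + 0.5))


def stratified_split(
    labels: CohortLabels, ratio: tuple[int, int] = (2, 1), seed: int = 0
) -> SplitAssignment:
    """Stratified seeded split of a labeled cohort.

    Within each class, the training partition receives
    ``round_half_up(n_class * r_train / (r_train + r_val))`` samples and the
    validation partition the remainder; membership within a class is a
    seeded uniform shuffle.
    """
    r_train, r_val = int(ratio[0]), int(ratio[1])
    if r_train <= 0 or r_val <= 0:
        raise ValueError("ratio components must be positive")
    if labels.n_cases == 0 or labels.n_controls == 0:
        raise ValueError("both classes must be present to split")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    val_ids: list[str] = []
    ids = np.asarray(labels.sample_ids, dtype=object)
    for cls in (1, 0):
        cls_ids = ids[labels.status == cls]
        if len(cls_ids) < 2:
            raise ValueError(f"class {cls} has < 2 samples; cannot stratify")
        n_train = round_half_up(len(cls_ids) * r_train / (r_train + r_val))
        perm = rng.permutation(len(cls_ids))
        train_ids.extend(cls_ids[perm[:n_train]])
        val_ids.extend(cls_ids[perm[n_train:]])
    return SplitAssignment(train_ids, val_ids, (r_train, r_val), int(seed))


def fit_normalization(
    matrix: ExpressionMatrix, train_ids: Sequence[str]
) -> NormalizationParams:
    """Fit per-feature min/max on the training samples only."""
    sub = matrix.subset_samples(train_ids)
    minima = sub.values.min(axis=1)
    maxima = sub.values.max(axis=1)
    flat = np.flatnonzero(~(maxima > minima))
    if flat.size:
        raise ValueError(
            f"feature {sub.feature_ids[int(flat[0])]!r} is constant on the "
            "training partition"
        )
    return NormalizationParams(list(matrix.feature_ids), minima, maxima)


def apply_normalization(
    matrix: ExpressionMatrix, params: NormalizationParams
) -> ExpressionMatrix:
    """Scale each feature to [0, 1] with the fitted params, clipping overflow.

    Validation samples falling outside the training range map to the 0/1
    boundary so downstream RBF units only ever see their fitted domain.
    """
    index = {f: i for i, f in enumerate(params.feature_ids)}
    try:
        rows = [index[f] for f in matrix.feature_ids]
    except KeyError as exc:
        raise KeyError(
            f"feature {exc.args[0]!r} missing from normalization params"
        ) from None
    mins = params.minima[rows][:, None]
    maxs = params.maxima[rows][:, None]
    scaled = np.clip((matrix.values - mins) / (maxs - mins), 0.0, 1.0)
    return ExpressionMatrix(list(matrix.feature_ids), list(matrix.sample_ids), scaled)
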