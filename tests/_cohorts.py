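"""Shared synthetic-cohort factories for the test suite."""

from mircascade import SyntheticSpec


def marker_spec(
    seed: int,
    n_cases: int = 600,
    n_controls: int = 1200,
    n_features: int = 200,
    marker_auc: float = 0.97,
    dup_auc: float = 0.955,
    n_markers: int = 3,
) -> SyntheticSpec:
    """Cohort with ``n_markers`` non-collinear planted markers, each with one
    collinear duplicate, among null features."""
    planted: dict[str, float] = {}
    blocks: list[list[str]] = []
    for i in range(n_markers):
        marker = f"miR-sim-{i:04d}"
        dup = f"miR-sim-{i + n_markers:04d}"
        planted[marker] = marker_auc
        planted[dup] = dup_auc
        blocks.append([marker, dup])
    return SyntheticSpec(
        n_cases=n_cases,
        n_controls=n_controls,
        n_features=n_features,
        planted_markers=planted,
        collinear_blocks=blocks,
        seed=seed,
    )
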