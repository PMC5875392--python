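import numpy as np
import pytest

from mircascade import CohortLabels, ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        feature_ids=["fA", "fB", "fC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [2.0, 4.0, 6.0, 8.0],
                [1.5, 1.0, 0.5, 2.5],
                [10.0, 30.0, 20.0, 40.0],
            ]
        ),
    )


@pytest.fixture
def tiny_labels() -> CohortLabels:
    return CohortLabels(["s1", "s2", "s3", "s4"], np.array([0, 0, 1, 1]))
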