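import numpy as np
import pandas as pd
import pytest

from emstate import (
    ExpressionMatrix,
    SyntheticSpec,
    generate_clone_matrix,
    generate_cohort,
    generate_cq_plate,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 genes x 5 samples, hand-constructed values."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 3.0, 4.0],
            "s2": [1.0, 2.0, 3.0, 4.0],
            "s3": [2.0, 3.0, 4.0, 5.0],
            "s4": [0.0, 1.0, 2.0, 3.0],
            "s5": [5.0, 5.0, 5.0, 5.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    labels = pd.Series(
        ["grp1", "grp1", "grp1", "grp2", "grp2"],
        index=values.columns,
    )
    return ExpressionMatrix(values, labels)


@pytest.fixture(scope="session")
def recovery_matrix():
    """Planted-signal clone matrix at the module's worked-example
    conditions: 1000 genes, +3 log2 shift, observation sd 0.5, 6 vs 4.
    Median-centered first, as in the pipeline, to strip the per-sample
    array offsets the generator plants."""
    from emstate import normalize_arrays

    spec = SyntheticSpec(seed=11, noise_sd=0.5)
    matrix, truth = generate_clone_matrix(spec)
    return normalize_arrays(matrix), truth


@pytest.fixture(scope="session")
def small_cohort():
    """Cohort with a planted score-hazard link (beta=0.7, n=300)."""
    return generate_cohort(SyntheticSpec(seed=5))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no score-survival association."""
    return generate_cohort(SyntheticSpec(seed=7, beta=0.0))


@pytest.fixture(scope="session")
def default_plate():
    return generate_cq_plate(SyntheticSpec(seed=3))
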