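import numpy as np
import pandas as pd
import pytest

from protosig import ExpressionMatrix, SampleAnnotation


@pytest.fixture
def small_matrix():
    """3 proteins x 6 samples with one missing entry."""
    data = pd.DataFrame(
        {
            "s1": [1.0, 2.0, -1.0],
            "s2": [1.5, np.nan, -0.5],
            "s3": [0.5, 1.0, 0.0],
            "s4": [2.0, 3.0, 1.0],
            "s5": [1.0, 2.5, 0.5],
            "s6": [0.0, 2.0, -1.5],
        },
        index=pd.Index(["pA", "pB", "pC"], name="protein_id"),
    )
    return ExpressionMatrix(data)


@pytest.fixture
def six_sample_annotation():
    return SampleAnnotation(
        pd.Series(
            ["A", "A", "B", "B", "C", "C"],
            index=pd.Index([f"s{i}" for i in range(1, 7)], name="sample_id"),
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_matrix(rng, n_proteins=50, n_samples=8, missing_fraction=0.2):
    values = rng.normal(size=(n_proteins, n_samples))
    mask = rng.random(values.shape) < missing_fraction
    values[mask] = np.nan
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=pd.Index([f"P{i:03d}" for i in range(n_proteins)], name="protein_id"),
            columns=[f"S{j}" for j in range(n_samples)],
        )
    )
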