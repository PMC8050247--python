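import numpy as np
import pandas as pd
import pytest

from metmix import FeatureMatrix, PhenotypeTable


@pytest.fixture
def separable_cohort():
    """Three balanced classes, each marked by one exclusive always-present feature.

    Three classes (not two) so no marker feature is the complement of
    another — each class's own marker is then the unique sparsest predictor.
    """
    vals = np.zeros((4, 24), dtype=np.int8)
    vals[0, :8] = 1  # fa present in every class-A sample
    vals[1, 8:16] = 1  # fb present in every class-B sample
    vals[2, 16:] = 1  # fc present in every class-C sample
    sample_ids = [f"s{i:02d}" for i in range(24)]
    X = FeatureMatrix(vals, ["fa", "fb", "fc", "fd"], sample_ids)
    meta = PhenotypeTable(
        pd.DataFrame(
            {"label": ["A"] * 8 + ["B"] * 8 + ["C"] * 8, "dataset_id": "d0"},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return X, meta


@pytest.fixture
def tiny_matrix():
    return FeatureMatrix(
        np.array([[1, 0], [0, 1]], dtype=np.int8), ["f1", "f2"], ["s1", "s2"]
    )


def random_decomposition_problem(rng, d, n_rows=20):
    """Random small problem with both feature classes present in c."""
    from metmix import DecompositionProblem

    while True:
        D = (rng.random((n_rows, d)) < 0.4).astype(float)
        c = (rng.random(n_rows) < 0.4).astype(float)
        if 0 < c.sum() < n_rows and D.any():
            return DecompositionProblem(
                D=D, c=c, lam=float(rng.uniform(0.02, 0.3))
            )
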