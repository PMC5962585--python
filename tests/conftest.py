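import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260)


@pytest.fixture
def small_matrix():
    """3 RNAs x 2 experiments with one missing cell."""
    return pd.DataFrame(
        [[1.0, -0.5], [np.nan, 0.25], [2.0, 1.5]],
        index=["rnaA", "rnaB", "rnaC"],
        columns=["exp1", "exp2"],
    )


def random_matrix(rng, n_rows, n_cols, missing=0.1):
    values = rng.normal(size=(n_rows, n_cols))
    if missing > 0:
        values[rng.random(values.shape) < missing] = np.nan
    return pd.DataFrame(
        values,
        index=[f"r{i:03d}" for i in range(n_rows)],
        columns=[f"c{j:03d}" for j in range(n_cols)],
    )


@pytest.fixture
def make_matrix(rng):
    def _make(n_rows=20, n_cols=10, missing=0.1):
        return random_matrix(rng, n_rows, n_cols, missing)

    return _make
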