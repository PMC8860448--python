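import numpy as np
import pandas as pd
import pytest

from proxprot import pipeline
from proxprot.io import IntensityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(values: np.ndarray, sample_ids=None) -> IntensityMatrix:
    """Build an IntensityMatrix from a plain array (helper for tests)."""
    n, m = values.shape
    pids = [f"P{i}" for i in range(n)]
    cols = sample_ids or [f"S{j}" for j in range(m)]
    df = pd.DataFrame(values, index=pd.Index(pids, name="protein_id"), columns=cols)
    genes = pd.Series([f"G{i}" for i in range(n)], index=df.index)
    return IntensityMatrix(values=df, gene_symbols=genes)


@pytest.fixture(scope="session")
def synthetic_run():
    """One full synthetic-study analysis, shared across tests."""
    return pipeline.run_synthetic(seed=1)
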