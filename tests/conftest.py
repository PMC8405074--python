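import numpy as np
import pandas as pd
import pytest

from netmark.io_formats import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def matrix_from_array(values, genes=None, samples=None, groups=None):
    """Build an ExpressionMatrix from a raw array for tests."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    groups = groups or {s: "all" for s in samples}
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), groups=groups
    )


@pytest.fixture
def make_matrix():
    return matrix_from_array
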