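import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_expression(rng, n_genes=10, n_samples=20, ties=False):
    """Random non-negative expression matrix; with ties=True values are
    rounded to one digit and zero-inflated, as in real RNA-seq tables."""
    vals = rng.lognormal(0.0, 1.0, size=(n_genes, n_samples))
    if ties:
        vals = np.round(vals, 1)
        vals[rng.uniform(size=vals.shape) < 0.2] = 0.0
    return pd.DataFrame(
        vals,
        index=[f"G{i + 1:03d}" for i in range(n_genes)],
        columns=[f"S{j + 1:03d}" for j in range(n_samples)],
    )


@pytest.fixture
def small_expr(rng):
    return make_expression(rng, n_genes=6, n_samples=8)
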