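import numpy as np
import pandas as pd
import pytest

from basalshift.io_formats import ExpressionMatrix, GeneSet
from basalshift.synthetic_data import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """A reduced-universe config for fast unit-level simulations."""
    return SimulationConfig(
        n_genes=200,
        n_basal_genes=20,
        n_luminal_genes=15,
        n_immune_genes=25,
    )


def make_matrix(values, genes=None, samples=None, scale="log2"):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    genes = genes or [f"g{i:03d}" for i in range(p)]
    samples = samples or [f"s{j:02d}" for j in range(n)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale=scale)


@pytest.fixture
def random_toy(rng):
    def _make(p=20, n=5, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return make_matrix(r.normal(8, 2, size=(p, n)))

    return _make
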