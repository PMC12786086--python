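import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scpotency import CountMatrix, PotencyAnalysis, SimConfig, simulate_experiment
from scpotency.qc import ExpressionMatrix


def small_sim_config(seed: int = 7, **overrides) -> SimConfig:
    """A fast, reduced-size study for unit tests (not the acceptance conditions)."""
    defaults = dict(
        n_cells_per_sample=400,
        n_genes=300,
        n_mito_genes=5,
        n_ribo_genes=10,
        markers_per_type=4,
        n_true_degs_per_celltype=30,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_exp():
    return simulate_experiment(small_sim_config())


@pytest.fixture(scope="session")
def small_results(small_exp):
    return PotencyAnalysis.from_simulation(small_exp).fit()


@pytest.fixture
def random_count_matrix():
    rng = np.random.default_rng(11)
    values = sp.random(100, 50, density=0.2, random_state=np.random.RandomState(11))
    values = sp.csr_matrix(np.round(values.toarray() * 10))
    genes = [f"G{i:03d}" for i in range(100)]
    cells = [f"BC{i:03d}" for i in range(50)]
    return CountMatrix(values, genes, cells)


def expression_from_array(values, scale="CPM", transgene_id=None, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cells = cells or [f"C{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values, genes, cells, scale, transgene_id)


@pytest.fixture
def cells_one_type():
    def make(n_a, n_b, cell_type="Rods"):
        n = n_a + n_b
        return pd.DataFrame(
            {
                "barcode": [f"C{i}" for i in range(n)],
                "sample": ["D"] * n_a + ["C"] * n_b,
                "genotype": ["KO"] * n_a + ["control"] * n_b,
                "treatment": ["NT"] * n,
                "cell_type": [cell_type] * n,
            }
        )

    return make
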