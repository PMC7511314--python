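import numpy as np
import pytest

from coexpheno.expression import ExpressionMatrix
from coexpheno.synthetic import SimulationConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def tiny_counts():
    """3 genes x 2 samples with known values."""
    return ExpressionMatrix(
        np.array([[10.0, 0.0], [5.0, 7.0], [0.0, 3.0]]),
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2"],
    )


@pytest.fixture(scope="session")
def signature():
    """Synthetic leukocyte signature: 40 genes x 5 cell types.

    Each cell type gets a block of strongly over-expressed marker genes on a
    shared lognormal baseline, so columns are well separated.
    """
    rng = np.random.default_rng(7)
    n_genes, n_types = 40, 5
    base = rng.lognormal(mean=3.0, sigma=0.4, size=(n_genes, 1))
    values = np.tile(base, (1, n_types))
    for t in range(n_types):
        markers = slice(t * 8, (t + 1) * 8)
        values[markers, t] *= rng.uniform(5.0, 10.0, size=8)
    return ExpressionMatrix(
        values,
        gene_ids=[f"sig{i:02d}" for i in range(n_genes)],
        sample_ids=["neutrophil", "lymphocyte", "monocyte", "eosinophil", "basophil"],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Default-parameter cohort scaled down for unit tests."""
    cfg = SimulationConfig(
        n_samples=80,
        n_genes=500,
        n_modules=3,
        module_sizes=[80, 60, 50],
        seed=11,
        phenotype_effects={"attention_problems": [(0, 1.2)], "aggressive_behavior": [(1, 1.0)]},
    )
    return generate_cohort(cfg)
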