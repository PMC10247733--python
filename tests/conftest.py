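import numpy as np
import pytest
from hypothesis import settings

from haplocycle.config import SimConfig
from haplocycle.cycle import SignatureFilterParams, filter_signature, score_phases
from haplocycle.imputation import DiffusionParams, drop_constant_genes, impute_counts
from haplocycle.synthetic import simulate_cells

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small two-ploidy simulation shared across test modules."""
    cfg = SimConfig(
        seed=123, n_cells_per_group=300, n_genes=300,
        n_signature_genes_per_phase=15,
    )
    return simulate_cells(cfg)


@pytest.fixture(scope="session")
def small_imputed(small_sim):
    adata, truth = small_sim
    out = impute_counts(adata, DiffusionParams())
    return drop_constant_genes(out), truth


@pytest.fixture(scope="session")
def small_scored(small_imputed):
    adata, truth = small_imputed
    sigs = [filter_signature(adata, s, SignatureFilterParams())
            for s in truth.phase_gene_sets()]
    return adata, truth, sigs, score_phases(adata, sigs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
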