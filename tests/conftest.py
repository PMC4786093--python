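import numpy as np
import pytest

from codonfit import HexamerAffinityModel, SimulationConfig, TRNAAbundanceTable
from codonfit.simulate import make_biased_gene_set


@pytest.fixture(scope="session")
def affinity_model():
    return HexamerAffinityModel.default()


@pytest.fixture(scope="session")
def trna_table():
    return TRNAAbundanceTable.default()


@pytest.fixture(scope="session")
def gene_set():
    """Ten seeded 100-codon genes with the default biased usage."""
    cfg = SimulationConfig(seed=42, n_genes=10, gene_length=100)
    return make_biased_gene_set(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
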