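import numpy as np
import pytest

from fluoromics import OJIPModelParams, PlantedOmicsDesign, gen_ojip_transient, gen_omics_dataset
from fluoromics._utils import log_time_grid


@pytest.fixture
def default_params():
    return OJIPModelParams()


@pytest.fixture
def cardinal_grid():
    """Log-spaced grid that contains the K/J/I times exactly."""
    return np.unique(np.concatenate([log_time_grid(), [3e-4, 2e-3, 3e-2]]))


@pytest.fixture
def healthy_transient(default_params, cardinal_grid):
    return gen_ojip_transient(default_params, cardinal_grid, label="A")


@pytest.fixture
def small_omics():
    design = PlantedOmicsDesign(
        n_transcripts=30, n_proteins=20, n_metabolites=15,
        planted_log2fc={"protein": {"prot_0000": 2.0}},
        tf_target_map={"gene_0010": [("gene_0011", 1.0), ("gene_0012", -1.0)]},
        coupled_genes=("gene_0020", "gene_0021"),
        coupled_metabolites=("met_0005", "met_0006"),
        gene_metabolite_coupling=1.5,
        sigma=0.1,
        seed=42,
    )
    return design, gen_omics_dataset(design)
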