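import numpy as np
import pytest

from nilnet.data_io import CountMatrix, study_design
from nilnet.synthetic_data import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def planted_sim():
    """A small planted-effect dataset shared by the DE/SPE unit tests.

    Strong (8-fold) allele effects so that recovery checks probe correctness,
    not the power limit of the 7-sample layout.
    """
    cfg = SimulationConfig(
        n_genes=400, n_allele=40, n_nil=40, n_interaction=40,
        n_spe_f288=5, n_spe_f271=3, allele_log2fc=3.0, seed=11,
    )
    cm, design, truth = simulate_counts(cfg)
    return cfg, cm, design, truth


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(0)
    counts = rng.poisson(100, size=(50, 7))
    design = study_design()
    return CountMatrix([f"g{i}" for i in range(50)],
                       [d.sample_id for d in design], counts), design
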