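import numpy as np
import pytest

import celldecon as cd


@pytest.fixture(scope="session")
def tiny_sim():
    """Small synthetic dataset shared across tests: 4 individuals,
    3 cell types, 100 cells each, 200 genes, 10 markers per type."""
    cfg = cd.ScSimConfig(
        n_individuals=4,
        n_cell_types=3,
        cells_per_individual=100,
        n_genes=200,
        n_markers_per_type=10,
        seed=11,
    )
    return cfg, *cd.simulate_sc(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
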