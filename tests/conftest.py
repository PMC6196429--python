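import numpy as np
import pytest

from dimorphnet import simulate


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort shared by read-only tests."""
    cfg = simulate.SimConfig(
        seed=42, n_samples=120, n_genes=300, n_snps=5000,
        module_sizes=(30, 50), trait_modules=(0, 1),
        n_pathways=10, enriched_pathways=(0,), n_disease_genes=40,
        n_drivers=2, hub_degree=30,
    )
    return cfg, simulate.simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
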