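import numpy as np
import pytest

from gvitgp import autodiff
from gvitgp.synthetic_data import SimConfig, simulate_dataset, simulate_genotypes


@pytest.fixture
def float64_autodiff():
    """Finite-difference gradient checks need float64 headroom."""
    autodiff.set_default_dtype(np.float64)
    yield
    autodiff.set_default_dtype(np.float32)


@pytest.fixture(scope="session")
def small_dataset():
    """Kinship-structured cohort small enough for fast protocol tests."""
    cfg = SimConfig(
        n_families=25, offspring_per_family=6, n_founders_per_family=2,
        n_markers=300, n_chromosomes=5, ld_rho=0.3,
        n_causal_additive=10, n_causal_epistatic_pairs=2,
        h2=0.7, missing_rate=0.02, seed=11,
    )
    g, pheno, truth = simulate_dataset(cfg)
    return g, pheno, truth, cfg


@pytest.fixture(scope="session")
def unrelated_panel():
    """No families, no LD: each sample is an independent HWE draw."""
    cfg = SimConfig(
        n_families=500, offspring_per_family=0, n_founders_per_family=1,
        n_markers=400, n_chromosomes=4, ld_rho=0.0,
        n_causal_additive=10, n_causal_epistatic_pairs=0,
        h2=0.5, missing_rate=0.0, seed=7,
    )
    g, truth = simulate_genotypes(cfg)
    return g, cfg
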