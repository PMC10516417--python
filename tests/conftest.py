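import numpy as np
import pytest

from rvbf.simulate import MafSpectrum, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_null_cohort():
    """A small null (no causal genes) cohort shared across tests."""
    config = SimulationConfig(
        n_cases=300,
        n_controls=300,
        n_genes=20,
        sites_per_gene=25,
        maf_spectrum=MafSpectrum.rare_only(),
        quality_model=None,
        seed=11,
    )
    return simulate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
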