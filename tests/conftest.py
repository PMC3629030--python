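import numpy as np
import pytest

from candgene.simulate import QTLSpec, SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared across tests (150 individuals,
    30 SNPs, 2 planted QTL, 300 progeny)."""
    config = SimulationConfig(
        seed=20260901,
        n_individuals=150,
        n_snps=30,
        n_progeny=300,
        qtl_effects=(QTLSpec(5, 2, 0.5, 0.2), QTLSpec(20, 4, 0.6, 0.0)),
    )
    return simulate_study(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(4235)
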