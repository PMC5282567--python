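import numpy as np
import pytest

from cernet.simulate import SimulationConfig, generate_expression, generate_sequences


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast configuration for pipeline-level tests."""
    return SimulationConfig(seed=7, n_case=10, n_control=10, n_mirna=40,
                            n_lncrna=60, n_mrna=150, frac_de=0.15, n_triads=8,
                            utr_length=200, lnc_length=300)


@pytest.fixture(scope="session")
def default_sim():
    """The study-scale simulation (2000 features, 20 vs 20) used by the
    recovery tests; generated once per session."""
    config = SimulationConfig(seed=11)
    mirna, lnc, mrna, truth = generate_expression(config)
    return config, mirna, lnc, mrna, truth


@pytest.fixture(scope="session")
def default_sim_sequences(default_sim):
    config, _, _, _, truth = default_sim
    return generate_sequences(config, truth)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
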