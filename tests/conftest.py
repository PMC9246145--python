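import numpy as np
import pytest

from codonregimes import GeneticCode, SimulationScenario, simulate_count_table


@pytest.fixture(scope="session")
def standard_code() -> GeneticCode:
    return GeneticCode.from_name("standard")


@pytest.fixture(scope="session")
def ctg_ser_code() -> GeneticCode:
    return GeneticCode.from_name("ctg_ser")


@pytest.fixture(scope="session")
def small_single_regime():
    """A small single-regime synthetic genome shared across tests."""
    sc = SimulationScenario(n_genes=120, n_chromosomes=3, n_regimes=1,
                            regime_proportions=(1.0,), seed=7)
    return simulate_count_table(sc)


@pytest.fixture(scope="session")
def small_two_regime():
    """A small two-regime genome with a strong GC3 gap."""
    sc = SimulationScenario(
        n_genes=400, n_chromosomes=4, n_regimes=2, regime_proportions=(0.6, 0.4),
        gc_shift=1.0, mean_block_length=40.0, seed=13,
    )
    return simulate_count_table(sc)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
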