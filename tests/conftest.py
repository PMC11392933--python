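import numpy as np
import pytest

from mga.synthetic_data import SimConfig, Simulator


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A desk-scale simulation shared by tests that only read its outputs."""
    return SimConfig(
        cells_per_type=24,
        n_peaks=600,
        n_genes=120,
        n_loci=4,
        variants_per_locus=20,
        n_links=12,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_sim(small_config) -> Simulator:
    sim = Simulator(small_config)
    sim.multiome()
    sim.gwas()
    sim.sequences()
    return sim


@pytest.fixture(scope="session")
def small_bundle(small_sim):
    return small_sim.multiome()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
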