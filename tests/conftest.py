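import numpy as np
import pytest

from seedreg.simulate import SimulationConfig, simulate_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A reduced-size study configuration shared across module tests."""
    return SimulationConfig(
        seed=7,
        chrom_length=400_000,
        n_genes=60,
        te_counts={"RC/Helitron": 40, "LTR/Gypsy": 30, "DNA/MuDR": 30},
        peak_count=50,
        n_expressed_genes=50,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)
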