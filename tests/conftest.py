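import numpy as np
import pytest

from zwscan import SimConfig, simulate_population


@pytest.fixture
def small_config():
    """A cheap 2 Mb chromosome with a 1 Mb sex region."""
    return SimConfig(
        genome_length=2_000_000,
        sex_region=(500_000, 1_500_000),
        n_zw_sites=100,
        n_background_snps=200,
        te_base_rate=0.2,
        te_peak_rate=0.8,
        te_peak_intervals=[(700_000, 900_000)],
        inversion_segment=(500_000, 1_200_000),
        query_expansion_bp=100_000,
        seed=7,
    )


@pytest.fixture
def small_truth(small_config):
    return simulate_population(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
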