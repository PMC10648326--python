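import numpy as np
import pytest

from her2mbc import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort shared across read-only tests."""
    params = syn.SimulationParams(
        n_samples=150, n_profile_genes=200, effect_genes=40,
        chr17_passenger_genes=10, n_signature_genes=10, seed=11,
    )
    return syn.simulate_cohort(params)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
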