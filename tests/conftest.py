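import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_coupled_cohort():
    """One seeded cohort with heart->face coupling, shared across tests."""
    from mmskit.synth import CouplingSpec, SyntheticCohortConfig, gen_coupled_cohort

    cfg = SyntheticCohortConfig(
        n_participants=3,
        duration=120.0,
        seed=2024,
        coupling=CouplingSpec("heart->face", lag=5, strength=0.8),
    )
    return gen_coupled_cohort(cfg)
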