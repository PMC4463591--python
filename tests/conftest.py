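import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chondrospec import default_config, default_grid
from chondrospec.synth import Design

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def small_config():
    """Reduced design (3 grades × 2 specimens × 5 cells) for fast tests."""
    from dataclasses import replace

    return replace(
        default_config(seed=1234),
        design=Design(specimens_per_grade=2, cells_per_specimen=5),
    )


@pytest.fixture(scope="session")
def noiseless_config():
    """All stochastic terms off: pure grade-dependent peak sums, unit gain."""
    from dataclasses import replace

    from chondrospec.synth import CosmicRayConfig

    return replace(
        default_config(seed=99),
        specimen_effect_sd=0.0,
        cell_effect_sd=0.0,
        specimen_composition_sd=0.0,
        cell_composition_sd=0.0,
        gain_range=(1.0, 1.0),
        baseline_coeff_sds=(0.0, 0.0, 0.0),
        noise_sd=0.0,
        cosmic_ray=CosmicRayConfig(prob_per_spectrum=0.0),
    )


@pytest.fixture(scope="session")
def gain_varied_config(noiseless_config):
    """Noiseless except for the multiplicative gain and a random baseline —
    exactly the structure EMSC is built to remove."""
    from dataclasses import replace

    return replace(
        noiseless_config, gain_range=(0.7, 1.3), baseline_coeff_sds=(0.5, 0.2, 0.1)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
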