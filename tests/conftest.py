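import numpy as np
import pytest
from hypothesis import settings

from cyclefate import SimConfig, simulate_cohort

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

ZERO_NOISE = {
    k: 0.0 for k in ("Cdt1", "Geminin", "SLBP", "H1", "cdk2_nuc", "cdk2_cyt", "p21")
}


def zero_noise_config(**kwargs):
    kwargs.setdefault("measurement_noise", dict(ZERO_NOISE))
    kwargs.setdefault("brightness_cv", 0.0)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def control_cohort():
    """Noisy control cohort, large enough for duration statistics."""
    return simulate_cohort(SimConfig(condition="control", n_mothers=500, rng_seed=101))


@pytest.fixture(scope="session")
def depletion_cohort():
    """Noisy glucose-depletion cohort with both mother-stage groups well
    populated (>=500 daughters per group)."""
    return simulate_cohort(
        SimConfig(condition="glucose_depletion", n_mothers=1300, rng_seed=202)
    )


@pytest.fixture(scope="session")
def small_clean_cohort():
    """Small noise-free depletion cohort for exactness checks."""
    return simulate_cohort(
        zero_noise_config(condition="glucose_depletion", n_mothers=40, rng_seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
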