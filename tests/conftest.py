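import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lungvar.cohort import LSC_IDS, CohortConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def isotropic_noise(sd_edibh: float, kappa: float) -> dict:
    """Controlled isotropic noise model with HFPV/eDIBH SD ratio kappa."""
    return {
        method: {sid: (sd, sd, sd) for sid in LSC_IDS}
        for method, sd in (("eDIBH", sd_edibh), ("HFPV", sd_edibh * kappa))
    }


@pytest.fixture(scope="session")
def small_cohort():
    """5-subject cohort with default (anisotropic) noise, fixed seed."""
    config = CohortConfig(n_subjects=5, sex_split=(3, 2), seed=7)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Noise-free, identity-setup cohort: landmarks equal canonical anatomy."""
    config = CohortConfig(
        n_subjects=3,
        sex_split=(2, 1),
        method_noise_sd=isotropic_noise(0.0, 1.0),
        setup_translation_sd=0.0,
        setup_rotation_sd=0.0,
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
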