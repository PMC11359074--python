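import numpy as np
import pytest

from gaitpcr.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-noise cohort, small enough for fast LOOCV tests."""
    return generate_cohort(CohortSpec(n_subjects=40, seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noise-free linear cohort: the estimator is exactly correctly specified."""
    spec = CohortSpec(n_subjects=40, accel_noise_sd=0.0, output_noise_sd=0.0,
                      seed=21)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
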