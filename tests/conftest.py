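import numpy as np
import pytest

from rteeg.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Tiny cohort: 2 subjects x 3 trials of 2-s recordings."""
    return GeneratorConfig(n_subjects=2, n_trials_per_subject=3, duration=2.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
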