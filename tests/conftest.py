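import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_config():
    from tmsnet.synthetic import CohortConfig
    return CohortConfig(
        n_subjects=8, n_voxels=40, n_regions=8, n_timepoints_rest=100,
        n_timepoints_task=120, n_informative=2, effect_weights=(-0.5, 0.5),
        anticorrelated_pairs=1, seed=3)


@pytest.fixture(scope="session")
def toy_cohort(toy_config):
    from tmsnet.synthetic import generate_cohort
    return generate_cohort(toy_config)


@pytest.fixture(scope="session")
def toy_clean(toy_cohort):
    from tmsnet.pipeline import preprocess_cohort
    return preprocess_cohort(toy_cohort, ("sham", "tms"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
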