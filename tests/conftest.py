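import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def atlas():
    from zfpdx.atlas import default_atlas

    return default_atlas()


@pytest.fixture(scope="session")
def small_study():
    """A seven-sample study mirroring the pilot cohort, scaled small."""
    from zfpdx.reference import table1_like_profiles
    from zfpdx.synthdata import StudyConfig, gen_study

    cfg = StudyConfig(
        profiles=table1_like_profiles(),
        n_embryos_per_sample=24,
        n_embryos_scored=6,
        n_flow_events=8000,
        seed=11,
    )
    return gen_study(cfg)
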