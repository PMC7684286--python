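import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def world():
    from pitchsub.world import build_world

    return build_world()


@pytest.fixture(scope="session")
def small_cohort():
    """Small deaf cohort (3 subs + 3 unsubs) for pipeline tests."""
    from dataclasses import replace

    from pitchsub.synthetic import default_cohort, simulate_cohort

    design = default_cohort(n_subs=3, n_unsubs=3, n_lo=0, n_nolo=0, n_subs_rand=0)
    design = [replace(p, renditions_per_day_mean=120.0) for p in design]
    return simulate_cohort(design, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
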