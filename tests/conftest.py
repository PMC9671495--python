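import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study():
    """A small planted-lag study shared by decoding/phase tests."""
    from thetasep.simulate import SimConfig, generate_study

    cfg = SimConfig(
        n_participants=3,
        n_trials_per_condition=6,
        n_channels=16,
        modulation_depth=0.6,
        planted_lag=np.deg2rad(34.0),
        pattern_snr=1.0,
        ref_snr=5.0,
        seed=11,
    )
    return generate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
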