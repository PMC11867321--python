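import pytest
from hypothesis import HealthCheck, settings

from jumpmetrics import JumpSpec, simulate_jump

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_cmj():
    return simulate_jump(JumpSpec(noise_sd=0.0))


@pytest.fixture(scope="session")
def noiseless_sj():
    return simulate_jump(JumpSpec.sj(noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_cmj():
    return simulate_jump(JumpSpec(noise_sd=3.0, seed=1))
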