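import pytest
from hypothesis import HealthCheck, settings

from p53loop import builtin_scenarios, default_parameters, resting_state

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def defaults():
    return default_parameters()


@pytest.fixture(scope="session")
def rest(defaults):
    return resting_state(defaults)


@pytest.fixture(scope="session")
def dna_damage():
    """The packaged (calibrated) DNA-damage scenario."""
    return builtin_scenarios()["dna_damage"]
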