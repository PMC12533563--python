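import pytest
from hypothesis import HealthCheck, settings

from inbdx import load_case_study

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def prostate():
    return load_case_study("prostate")


@pytest.fixture(scope="session")
def colorectal():
    return load_case_study("colorectal")


@pytest.fixture(scope="session")
def cad():
    return load_case_study("cad")
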