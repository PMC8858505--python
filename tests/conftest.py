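import pytest
from hypothesis import HealthCheck, settings

from subborrow import example_fixture, odyssey_planning_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def odyssey():
    return odyssey_planning_fixture()


@pytest.fixture(scope="session")
def example1():
    return example_fixture(1)


@pytest.fixture(scope="session")
def example2():
    return example_fixture(2)
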