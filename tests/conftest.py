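import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from flscost import FLSCostModel, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def model(params):
    return FLSCostModel(params)


@pytest.fixture(scope="session")
def base(model):
    return model.fit()
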