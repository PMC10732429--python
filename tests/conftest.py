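import pytest
from hypothesis import HealthCheck, settings

from merkelsim import MerkelCellModel, ModelParameters

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return ModelParameters.preset("fig2")


@pytest.fixture(scope="session")
def model(params):
    return MerkelCellModel(params)


@pytest.fixture(scope="session")
def rest_state(model):
    """The relaxed resting state of the default preset (computed once)."""
    return model.initialize_rest()
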