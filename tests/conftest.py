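import pytest
from hypothesis import settings

from psmcea import default_config

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from psmcea.icer import evaluate_base_case
from psmcea.psm import build_trace


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def base_case(config):
    """(CEResult, {arm: ArmOutcome}) for the shipped base-case fixture."""
    return evaluate_base_case(config)


@pytest.fixture(scope="session")
def traces(config):
    return {
        label: build_trace(config.arm_model(label), config.grid)
        for label in config.arm_labels
    }
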