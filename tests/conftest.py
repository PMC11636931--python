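import numpy as np
import pytest

from prfocus.experiments import ExperimentConfig, build_study


@pytest.fixture(scope="session")
def default_config():
    return ExperimentConfig()


@pytest.fixture(scope="session")
def studies(default_config):
    """The three seeded phantom studies of the default experiment design."""
    return [build_study(default_config, s) for s in default_config.phantom_seeds()]


@pytest.fixture(scope="session")
def study(studies):
    return studies[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
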