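import numpy as np
import pytest

from hevindex import (
    GeneratorProfile,
    generate_scenario_pair,
    generate_survey,
    khon_kaen_catalog,
)


@pytest.fixture(scope="session")
def catalog():
    return khon_kaen_catalog()


@pytest.fixture(scope="session")
def default_profile():
    return GeneratorProfile(seed=42)


@pytest.fixture(scope="session")
def survey42(default_profile):
    """Default synthetic survey (seed 42) plus its ground truth."""
    return generate_survey(default_profile)


@pytest.fixture(scope="session")
def scenario_pair(default_profile):
    return generate_scenario_pair(default_profile)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
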