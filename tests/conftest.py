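import numpy as np
import pytest

from niacffa import default_parameters
from niacffa.population import default_population_model


@pytest.fixture(scope="session")
def lean_params():
    return default_parameters("lean")


@pytest.fixture(scope="session")
def obese_params():
    return default_parameters("obese")


@pytest.fixture(scope="session")
def obese_popmodel():
    return default_population_model("obese")


@pytest.fixture(scope="session")
def lean_popmodel():
    return default_population_model("lean")
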