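import numpy as np
import pytest

from glassprobe.afga import build_stoichiometry, default_afga_model
from glassprobe.gordon_taylor import MoistureValue
from glassprobe.synthetic import DEFAULT_RELAX_TRUTH, DensitySchedule


@pytest.fixture(scope="session")
def stoich():
    """Glucose-polymer + water stoichiometry at the study moisture content."""
    return build_stoichiometry(MoistureValue(0.1069, "wet"))


@pytest.fixture(scope="session")
def afga_model(stoich):
    return default_afga_model(stoich)


@pytest.fixture(scope="session")
def relax_truth():
    return DEFAULT_RELAX_TRUTH


@pytest.fixture(scope="session")
def schedule():
    return DensitySchedule()


@pytest.fixture(scope="session")
def energy_grid():
    return np.geomspace(1e-3, 1000.0, 400)
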