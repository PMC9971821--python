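import numpy as np
import pytest

from dphpkin import ParameterSet
from dphpkin.calibration import build_calibration_priors, mcmc
from dphpkin.study import generate_study


@pytest.fixture(scope="session")
def default_params() -> ParameterSet:
    return ParameterSet.from_config()


@pytest.fixture(scope="session")
def study_data():
    """Synthetic four-volunteer study at the calibrated central estimates."""
    return generate_study(seed=11)


@pytest.fixture(scope="session")
def short_chain(study_data):
    """A deliberately short calibration chain shared by summary/band tests."""
    return mcmc(study_data, build_calibration_priors(), n_iter=3000, thin=10, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
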