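import numpy as np
import pytest

from afpom import cell_model as cm
from afpom import synthetic_data as sd


@pytest.fixture(scope="session")
def caf_params():
    """Chronic-AF remodeled baseline of the ionic model."""
    return cm.apply_caf_remodeling(cm.BaselineParameters())


@pytest.fixture(scope="session")
def caf_rest(caf_params):
    """Equilibrated resting state, shared across cell-model tests."""
    return cm.equilibrate(caf_params, 20_000.0)


@pytest.fixture(scope="session")
def caf_threshold(caf_params, caf_rest):
    """Diastolic threshold (pA/pF) of the remodeled baseline."""
    return cm.diastolic_threshold(caf_params, state=caf_rest)


@pytest.fixture(scope="session")
def surrogate():
    return sd.SurrogateParameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
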