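import numpy as np
import pytest

from stridesim.dynamics import CompiledModel, fit_model_geometry
from stridesim.synth import make_planar_fixture, make_reference_gait


@pytest.fixture(scope="session")
def fixture_spec():
    return make_planar_fixture()

@pytest.fixture(scope="session")
def fixture_geometry(fixture_spec):
    return fit_model_geometry(CompiledModel(fixture_spec))


@pytest.fixture(scope="session")
def cmodel(fixture_spec, fixture_geometry):
    return CompiledModel(fixture_spec, geometry=fixture_geometry)


@pytest.fixture(scope="session")
def reference():
    return make_reference_gait(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
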