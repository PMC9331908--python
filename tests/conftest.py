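import numpy as np
import pytest

import craspetherm as ct


@pytest.fixture(scope="session")
def fixture_dataset():
    return ct.thomas_fixture()


@pytest.fixture(scope="session")
def canonical_fit(fixture_dataset):
    """Boatman fit to the canonical noiseless dataset (shared; expensive)."""
    return ct.fit_model(fixture_dataset, "boatman_2017", n_starts=50, seed=1)


@pytest.fixture(scope="session")
def boatman():
    return ct.get_model("boatman_2017")


@pytest.fixture()
def small_geometry():
    return ct.GridGeometry(nrows=10, ncols=10, xll=-50.0, yll=-25.0, cellsize=5.0)


def constant_stack(value, geometry, **kw):
    layers = np.full((12, geometry.nrows, geometry.ncols), float(value))
    return ct.TemperatureRasterStack(layers, geometry, **kw)


@pytest.fixture()
def make_constant_stack(small_geometry):
    def _make(value, **kw):
        return constant_stack(value, small_geometry, **kw)

    return _make
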