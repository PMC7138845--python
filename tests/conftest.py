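import numpy as np
import pytest

import colomech as cm


@pytest.fixture(scope="session")
def material_sets():
    return cm.load_material_params()


@pytest.fixture(scope="session")
def set1(material_sets):
    return material_sets[0]


@pytest.fixture(scope="session")
def geom():
    return cm.TubeGeometry()


@pytest.fixture(scope="session")
def coarse_cylinder(geom):
    """Small quarter-cylinder mesh for fast solver tests."""
    return cm.build_normal_mesh(geom, 4.0)


@pytest.fixture(scope="session")
def coarse_pouch(geom):
    return cm.build_pouch_mesh(geom, cm.PouchSpec(10.0, 4.0), 3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def admissible_states(rng, n, lo=0.97, hi=1.05):
    """Random biaxial stretch states inside the fiber-exponential range."""
    lams = rng.uniform(lo, hi, size=(n, 2))
    return [cm.StretchState(a, b) for a, b in lams]
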