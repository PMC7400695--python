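import numpy as np
import pytest

from hemoflow.geometry import BifurcationGeometry, build_planform
from hemoflow.meshing import label_regions, triangulate


@pytest.fixture(scope="session")
def default_planform():
    return build_planform(BifurcationGeometry())


@pytest.fixture(scope="session")
def coarse_bifurcation_mesh(default_planform):
    """One labelled coarse mesh shared by solver/postprocessing tests."""
    return label_regions(triangulate(default_planform, 1.1e-3))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
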