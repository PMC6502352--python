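import numpy as np
import pytest

from icod import MutationalEffectVector, SectorSpec, SelectionSpec, enumerate_ensemble
from icod.ensembles import covariance
from icod.synthetic import make_delta, make_toy_structure


@pytest.fixture
def delta_l3():
    """The length-3 effect vector (-1, 1, 0) of the worked selection example."""
    return MutationalEffectVector(np.array([-1.0, 1.0, 0.0]))


@pytest.fixture
def zero_projection_ensemble(delta_l3):
    """The four equally weighted binary sequences with zero trait value:
    (0,0,0), (1,1,0), (0,0,1), (1,1,1)."""
    sel = SelectionSpec(form="rectangular", t_star=0.0, half_width=1e-9)
    return enumerate_ensemble(delta_l3, sel)


@pytest.fixture
def zero_projection_covariance(zero_projection_ensemble):
    return covariance(zero_projection_ensemble)


@pytest.fixture
def sector_delta():
    """Default synthetic sector vector: L=100, 20 sector sites, ratio 10."""
    return make_delta(SectorSpec(L=100, n_sector_sites=20, seed=11))


@pytest.fixture
def toy_structures():
    """20-residue helical toy structure and its locally displaced copy."""
    return make_toy_structure(20, "helix", seed=5)
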