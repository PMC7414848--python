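import numpy as np
import pytest

from distnet.distmap import DistanceMap, ProteinRecord, compute_distance_map
from distnet.synthetic import SyntheticSpec, make_protein


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def helix_record():
    """A 10-residue ideal alpha-helix (rise 1.5 A, 100 deg/residue, r=2.3 A)."""
    n = 10
    theta = np.deg2rad(100.0) * np.arange(n)
    coords = np.c_[2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * np.arange(n)]
    return ProteinRecord(id="helix10", sequence="ACDEFGHIKL",
                         cb_coords=coords, valid=np.ones(n, bool))


@pytest.fixture
def compact_record():
    return make_protein(SyntheticSpec(length=80, seed=7))


@pytest.fixture
def compact_dmap(compact_record):
    return compute_distance_map(compact_record)


def random_distance_map(rng, L, observed=1.0):
    """A symmetric pseudo distance map with zero diagonal and optional mask."""
    coords = rng.uniform(0, 30, size=(L, 3))
    from scipy.spatial.distance import cdist

    values = cdist(coords, coords)
    valid = rng.random(L) < observed
    mask = np.outer(valid, valid)
    values = np.where(mask, values, 0.0)
    return DistanceMap(values=values, mask=mask)
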