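import numpy as np
import pytest

from ensitemap.structure_io import assign_vdw_radii
from ensitemap.synthetic import HingeSpec, make_hinge_ensemble, make_toy_protein


@pytest.fixture(scope="session")
def toy_protein():
    return make_toy_protein(n_residues=24, seed=0)


@pytest.fixture(scope="session")
def hinge_fixture():
    """Default 7-member hinge ensemble, pocket open in members 0-4, noise-free."""
    return make_hinge_ensemble(HingeSpec(seed=0))


@pytest.fixture(scope="session")
def hinge_fixture_radii(hinge_fixture):
    """Same ensemble with vdW radii assigned on every member."""
    return [assign_vdw_radii(m) for m in hinge_fixture.ensemble.members]


def random_rigid_transform(rng):
    """A uniformly random proper rotation + bounded translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-10, 10, size=3)
    return R, t


def random_rmsd_matrix(rng, n):
    """A random symmetric non-negative matrix with zero diagonal (Å scale)."""
    a = np.abs(rng.normal(0.0, 2.0, size=(n, n)))
    v = np.triu(a, 1)
    v = v + v.T
    return v
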