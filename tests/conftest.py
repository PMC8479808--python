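import numpy as np
import pytest

from gagcg import (ElongationSpec, elongate, make_gag_helix,
                   make_peptide_complex, z1_forcefield)


@pytest.fixture(scope="session")
def ff():
    return z1_forcefield()


@pytest.fixture()
def dp6():
    """Synthetic all-atom dp6 GAG helix with ring atoms and glycosidic O."""
    return make_gag_helix(6, with_ring_atoms=True)


@pytest.fixture()
def peptide_complex(dp6):
    """GKGKG model peptide laid alongside the dp6 helix at 6 Å."""
    return make_peptide_complex("GKGKG", dp6, offset=6.0)


@pytest.fixture()
def dp16_mixed(dp6, ff):
    """dp6 core elongated with 10 reducing-end CG beads."""
    return elongate(dp6, ff, ElongationSpec(n_reducing=10))


def rigid_transform(rng):
    """Random rotation matrix + translation for invariance tests."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(scale=10.0, size=3)


def apply_rigid(complex_, rot, trans):
    out = complex_.copy()
    for atom in out.receptor_atoms + out.gag_atoms:
        atom.position = rot @ atom.position + trans
    return out
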