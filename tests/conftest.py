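import numpy as np
import pytest

from unbindkit import Topology


@pytest.fixture
def single_ion_topology():
    """One charged atom with a GB radius — the Born-equation test case."""
    def make(charge=1.0, gb_radius=1.5):
        return Topology(
            atom_names=["X1"], elements=["C"], res_ids=[1],
            res_names=["ION"], chain_ids=["A"], masses=[12.011],
            charges=[charge], lj_radius=[1.7], lj_epsilon=[0.1],
            gb_radius=[gb_radius])
    return make


@pytest.fixture
def sphere_topology():
    """N carbon spheres with given radii and pairwise-exact LCPO
    coefficients (P1=1, P2=-1, P3=P4=0)."""
    def make(radii, lcpo=(1.0, -1.0, 0.0, 0.0)):
        n = len(radii)
        return Topology(
            atom_names=[f"X{i + 1}" for i in range(n)], elements=["C"] * n,
            res_ids=list(range(1, n + 1)), res_names=["SPH"] * n,
            chain_ids=["A"] * n, masses=[12.011] * n,
            charges=[0.0] * n, lj_radius=np.asarray(radii, float),
            lj_epsilon=[0.1] * n, gb_radius=[1.5] * n,
            lcpo_params=np.tile(lcpo, (n, 1)))
    return make
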