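import numpy as np
import pytest

from clampkit import (
    OpeningSchedule,
    PlantedEvent,
    ToyClampParams,
    build_toy_clamp,
)
from clampkit.structure_io import select_ca
from clampkit.synthetic_clamp import default_plane_triplets, interface_groups


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       5.300   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       9.100   0.000   0.000  1.00  0.00           C
ATOM      5  CA  VAL A   4      12.900   0.000   0.000  1.00  0.00           C
ATOM      6  CA  LEU A   5      16.700   0.000   0.000  1.00  0.00           C
TER
ATOM      7  CA  THR B   1       1.500   4.000   0.000  1.00  0.00           C
ATOM      8  CA  PRO B   2       5.300   4.000   0.000  1.00  0.00           C
ATOM      9  CA  LYS B   3       9.100   4.000   0.000  1.00  0.00           C
ATOM     10  CA  ASP B   4      12.900   4.000   0.000  1.00  0.00           C
ATOM     11  CA  PHE B   5      16.700   4.000   0.000  1.00  0.00           C
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       0.500   0.000   0.000  0.60  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def two_chain_pdb(tmp_path):
    path = tmp_path / "two_chain.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture(scope="session")
def toy_params():
    return ToyClampParams(beads_per_arm=20, radius=30.0, noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def toy_clamp(toy_params):
    return build_toy_clamp(toy_params)


@pytest.fixture(scope="session")
def toy_setup(toy_params, toy_clamp):
    """Toy clamp plus its interface pair groups and plane triplets."""
    from clampkit import PlaneTriplet, extract_contact_pairs

    g1 = interface_groups(toy_params, 1)
    g2 = interface_groups(toy_params, 2)
    pairs1 = extract_contact_pairs(toy_clamp, *g1, 8.0, "interface1")
    pairs2 = extract_contact_pairs(toy_clamp, *g2, 8.0, "interface2")
    ta, tb = default_plane_triplets(toy_params)
    triplet_a = PlaneTriplet(tuple(select_ca(toy_clamp, ta).indices))
    triplet_b = PlaneTriplet(tuple(select_ca(toy_clamp, tb).indices))
    all_ca = select_ca(toy_clamp, list(range(1, 2 * toy_params.beads_per_arm + 1)))
    return {
        "params": toy_params,
        "struct": toy_clamp,
        "pairs1": pairs1,
        "pairs2": pairs2,
        "triplet_a": triplet_a,
        "triplet_b": triplet_b,
        "rmsd_sel": all_ca,
    }


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a translation up to 20 Å."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng)
    trans = rng.uniform(-20, 20, 3)
    return rot, trans
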