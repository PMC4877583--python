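import numpy as np
import pytest

from mdprep.builder import build_segment
from mdprep.fixtures import (
    build_toy_peptide,
    make_mini_topology,
    make_toy_peptide_pdb,
    mini_topology_set,
)
from mdprep.system_model import CoordStatus, MolecularSystem


@pytest.fixture(scope="session")
def topo():
    return mini_topology_set()


@pytest.fixture(scope="session")
def mini_topology_text():
    return make_mini_topology()


@pytest.fixture()
def peptide(topo):
    """Fully coordinated 3-residue toy peptide (GLY-ALA-CYS)."""
    return build_toy_peptide(3, resnames=["GLY", "ALA", "CYS"], topo=topo)


@pytest.fixture()
def peptide_pdb():
    return make_toy_peptide_pdb(3, resnames=["GLY", "ALA", "CYS"])


def seeded_peptide(topo, resnames, segid="P"):
    """Built-but-unplaced peptide with only the first backbone frame known."""
    system = MolecularSystem()
    build_segment(
        system, segid, [(i + 1, rn) for i, rn in enumerate(resnames)], topo,
        first_patch="NONE", last_patch="NONE",
    )
    system.atoms[system.find_atom(segid, 1, "N")].set_position(
        (0.0, 0.0, 0.0), CoordStatus.KNOWN
    )
    system.atoms[system.find_atom(segid, 1, "CA")].set_position(
        (1.45, 0.0, 0.0), CoordStatus.KNOWN
    )
    ang = np.radians(69.0)
    system.atoms[system.find_atom(segid, 1, "C")].set_position(
        (1.45 + 1.52 * np.cos(ang), 1.52 * np.sin(ang), 0.0), CoordStatus.KNOWN
    )
    return system
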