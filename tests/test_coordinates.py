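"""Geometry: IC placement, fixpoint guessing, hydrogen heuristics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdprep.builder import ICEntry, build_segment
from mdprep.coordinates import (
    DegenerateFrameError,
    MIN_BOND_ANGLE_DEG,
    assign_coordinates,
    bond_angle,
    bond_length,
    dihedral_angle,
    guess_hydrogens,
    place_from_ic,
    run_ic_guessing,
)
from mdprep.fixtures import make_toy_peptide_pdb
from mdprep.system_model import Atom, CoordStatus, MolecularSystem, read_pdb, write_pdb
from mdprep.topology import AliasMap, ICRecord

from conftest import seeded_peptide


# ---------------------------------------------------------------------------
# place_from_ic
# ---------------------------------------------------------------------------

def test_place_from_ic_reference_frame_cases():
    a, b, c = (0.0, 1.0, 0.0), (0.0, 0.0, 0.0), (1.0, 0.0, 0.0)
    d0 = place_from_ic(a, b, c, 1.0, 90.0, 0.0)
    assert d0 == pytest.approx([1.0, 1.0, 0.0], abs=1e-9)
    d180 = place_from_ic(a, b, c, 1.0, 90.0, 180.0)
    assert d180 == pytest.approx([1.0, -1.0, 0.0], abs=1e-9)


def test_place_from_ic_theta_180_extends_bc_line():
    a, b, c = (0.0, 1.0, 0.0), (0.0, 0.0, 0.0), (1.0, 0.0, 0.0)
    d = place_from_ic(a, b, c, 1.3, 180.0, 0.0)
    assert d == pytest.approx([2.3, 0.0, 0.0], abs=1e-9)
    assert bond_length(c, d) == pytest.approx(1.3, abs=1e-9)


def test_place_from_ic_collinear_frame_raises():
    with pytest.raises(DegenerateFrameError):
        place_from_ic((0, 0, 0), (1, 0, 0), (2, 0, 0), 1.0, 109.5, 60.0)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    st.integers(min_value=0, max_value=2**31 - 1),
    st.floats(0.5, 3.0),
    st.floats(5.0, 175.0),
    st.floats(-179.0, 179.0),
)
def test_place_from_ic_round_trip_property(frame_seed, r, theta, phi):
    """Recomputing (r, theta, phi) from the placed point matches inputs."""
    rng = np.random.default_rng(frame_seed)
    a, b, c = rng.normal(size=(3, 3)) * 3.0
    ang = bond_angle(a, b, c)
    if ang < 1.0 or ang > 179.0:
        return
    d = place_from_ic(a, b, c, r, theta, phi)
    assert bond_length(c, d) == pytest.approx(r, abs=1e-6)
    assert bond_angle(b, c, d) == pytest.approx(theta, abs=1e-6)
    measured = dihedral_angle(a, b, c, d)
    assert abs(((measured - phi + 180.0) % 360.0) - 180.0) < 1e-6


# ---------------------------------------------------------------------------
# assign_coordinates
# ---------------------------------------------------------------------------

def test_assignment_leaves_exactly_hydrogens_unknown(topo):
    system = seeded_peptide(topo, ["GLY", "ALA", "CYS"])
    for atom in system.atoms:  # start from a fully unknown build
        atom.clear_position()
    pdb = make_toy_peptide_pdb(3, resnames=["GLY", "ALA", "CYS"])
    stats = assign_coordinates(system, read_pdb(pdb), topo.aliases)
    n_h = sum(1 for a in system.atoms if a.mass < 3.5)
    assert stats.still_unknown == n_h
    assert stats.matched == system.n_atoms() - n_h
    assert not stats.unmatched_records


def test_assignment_resolves_stale_atom_names_via_alias(topo):
    system = MolecularSystem()
    build_segment(system, "W", [(1, "TP3W")], topo)
    text = (
        "ATOM      1  O   HOH W   1       1.000   2.000   3.000  1.00  0.00\n"
        "END\n"
    )
    aliases = AliasMap()
    aliases.add_atom_alias("HOH", "O", "OH2")
    stats = assign_coordinates(system, read_pdb(text), aliases)
    assert stats.matched == 1
    oh2 = system.atoms[system.find_atom("W", 1, "OH2")]
    assert oh2.position == pytest.approx([1.0, 2.0, 3.0])


def test_unmatched_record_reported_system_untouched(topo):
    system = MolecularSystem()
    build_segment(system, "W", [(1, "TP3W")], topo)
    text = (
        "ATOM      1  ZZ  FOO W   9       1.000   2.000   3.000  1.00  0.00\n"
        "END\n"
    )
    stats = assign_coordinates(system, read_pdb(text))
    assert stats.matched == 0
    assert stats.unmatched_records == [("W", 9, "ZZ")]
    assert all(a.coord_status == CoordStatus.UNKNOWN for a in system.atoms)


# ---------------------------------------------------------------------------
# run_ic_guessing
# ---------------------------------------------------------------------------

def test_guessing_places_all_hydrogens_from_ics(topo):
    system = seeded_peptide(topo, ["GLY", "ALA", "CYS"])
    report = run_ic_guessing(system, topo)
    assert report.n_remaining == 0
    hydrogens = [a for a in system.atoms if a.mass < 3.5]
    assert hydrogens and all(
        a.coord_status == CoordStatus.GUESSED for a in hydrogens
    )


def _angle_probe_system(theta_bcd: float) -> MolecularSystem:
    """Atoms B-C bonded, D bonded to C; one IC places D at angle theta."""
    system = MolecularSystem()
    for name, pos in (("A", (0.0, 1.0, 0.0)), ("B", (0.0, 0.0, 0.0)), ("C", (1.5, 0.0, 0.0))):
        i = system.add_atom(Atom(segid="T", resid=1, resname="PRB", name=name,
                                 type="X", mass=12.0))
        system.atoms[i].set_position(pos, CoordStatus.KNOWN)
    i_d = system.add_atom(Atom(segid="T", resid=1, resname="PRB", name="D",
                               type="X", mass=12.0))
    system.bonds = [(1, 2), (2, 3)]  # B-C and C-D: placing D makes angle B-C-D
    ic = ICRecord(("A", "B", "C", "D"), False, 1.5, 90.0, 60.0, theta_bcd, 1.2)
    key = lambda n: ("T", 1, "", n)
    system.ic_pool = [ICEntry((key("A"), key("B"), key("C"), key("D")), ic)]
    return system


def test_ic_rejected_when_bond_angle_below_45(topo):
    system = _angle_probe_system(40.0)
    report = run_ic_guessing(system, topo)
    assert report.n_remaining == 1
    assert ("T", 1, "D") in report.rejected_by_angle
    assert system.atoms[3].coord_status == CoordStatus.UNKNOWN


def test_ic_accepted_at_and_above_45(topo):
    for theta in (45.0, 46.0, 90.0):
        system = _angle_probe_system(theta)
        report = run_ic_guessing(system, topo)
        assert report.n_remaining == 0, theta
        assert system.atoms[3].coord_status == CoordStatus.GUESSED


def test_atom_without_ic_stays_unknown_and_writes_minus_one(topo):
    system = MolecularSystem()
    build_segment(system, "W", [(1, "TP3W")], topo)  # water IC needs -OH2
    report = run_ic_guessing(system, topo)
    assert report.n_remaining == 3
    text = write_pdb(system)
    occ = {line[54:60].strip() for line in text.splitlines() if line.startswith("ATOM")}
    assert occ == {"-1.00"}


def test_guessing_is_order_independent(topo):
    base = seeded_peptide(topo, ["GLY", "ALA", "CYS"])
    run_ic_guessing(base, topo)
    reference = base.coordinates()
    rng = np.random.default_rng(11)
    for _ in range(3):
        other = seeded_peptide(topo, ["GLY", "ALA", "CYS"])
        pool = list(other.ic_pool)
        rng.shuffle(pool)
        other.ic_pool = pool
        run_ic_guessing(other, topo)
        assert np.allclose(other.coordinates(), reference, atol=1e-6)


def test_guessing_never_touches_known_atoms(topo):
    system = seeded_peptide(topo, ["GLY", "ALA", "CYS"])
    known = {
        i: system.atoms[i].position.copy()
        for i in range(system.n_atoms())
        if system.atoms[i].coord_status == CoordStatus.KNOWN
    }
    run_ic_guessing(system, topo)
    for i, pos in known.items():
        assert system.atoms[i].coord_status == CoordStatus.KNOWN
        assert np.array_equal(system.atoms[i].position, pos)


def test_reverse_application_places_first_atom(topo):
    """An IC can fill atom a when b, c, d are known (reverse direction)."""
    system = MolecularSystem()
    positions = {"A": None, "B": (0.0, 0.0, 0.0), "C": (1.5, 0.0, 0.0),
                 "D": (2.0, 1.3, 0.0)}
    for name, pos in positions.items():
        i = system.add_atom(Atom(segid="T", resid=1, resname="PRB", name=name,
                                 type="X", mass=12.0))
        if pos is not None:
            system.atoms[i].set_position(pos, CoordStatus.KNOWN)
    system.bonds = [(0, 1), (1, 2), (2, 3)]
    ic = ICRecord(("A", "B", "C", "D"), False, 1.1, 100.0, 60.0, 95.0, 1.4)
    key = lambda n: ("T", 1, "", n)
    system.ic_pool = [ICEntry((key("A"), key("B"), key("C"), key("D")), ic)]
    report = run_ic_guessing(system, topo)
    assert report.n_remaining == 0
    a = system.atoms[0].position
    assert bond_length(a, positions["B"]) == pytest.approx(1.1, abs=1e-6)
    assert bond_angle(a, positions["B"], positions["C"]) == pytest.approx(100.0, abs=1e-6)
    assert dihedral_angle(a, positions["B"], positions["C"], positions["D"]) == pytest.approx(60.0, abs=1e-6)


def test_improper_forward_and_reverse_consistency():
    """Improper placement honors the recorded torsion of (a, b, c, d)."""
    rng = np.random.default_rng(5)
    b, c = rng.normal(size=(2, 3))
    a = c + rng.normal(size=3)
    d_true = c + rng.normal(size=3)
    phi = dihedral_angle(a, b, c, d_true)
    r_cd = bond_length(c, d_true)
    th_bcd = bond_angle(b, c, d_true)
    r_ac = bond_length(a, c)
    th_acb = bond_angle(a, c, b)
    # forward: rebuild d from (a, b, c)
    d_re = place_from_ic(a, b, c, r_cd, th_bcd, phi)
    assert d_re == pytest.approx(d_true, abs=1e-9)
    # reverse: rebuild a from (d, b, c) with the negated torsion
    a_re = place_from_ic(d_true, b, c, r_ac, th_acb, -phi)
    assert a_re == pytest.approx(a, abs=1e-9)


# ---------------------------------------------------------------------------
# guess_hydrogens
# ---------------------------------------------------------------------------

def _parent_with_neighbors(n_known: int, n_h: int, degree: int) -> MolecularSystem:
    system = MolecularSystem()
    i_p = system.add_atom(Atom(segid="T", resid=1, resname="PRB", name="P0",
                               type="C", mass=12.011))
    system.atoms[i_p].set_position((0.0, 0.0, 0.0), CoordStatus.KNOWN)
    if degree >= 4:
        # three vertices of a regular tetrahedron
        dirs = [
            np.array([1.0, 1.0, 1.0]),
            np.array([1.0, -1.0, -1.0]),
            np.array([-1.0, 1.0, -1.0]),
        ]
    else:
        # a planar 120-degree pair
        dirs = [
            np.array([1.0, 0.0, 0.0]),
            np.array([-0.5, np.sqrt(3) / 2, 0.0]),
        ]
    for k in range(n_known):
        i = system.add_atom(Atom(segid="T", resid=1, resname="PRB", name=f"X{k}",
                                 type="C", mass=12.011))
        system.atoms[i].set_position(1.5 * dirs[k] / np.linalg.norm(dirs[k]),
                                     CoordStatus.KNOWN)
        system.bonds.append((i_p, i))
    for k in range(n_h):
        i = system.add_atom(Atom(segid="T", resid=1, resname="PRB", name=f"H{k}",
                                 type="H", mass=1.008))
        system.bonds.append((i_p, i))
    assert len(system.bonds) == degree
    return system


def test_sp3_completion_spreads_all_four_directions():
    system = _parent_with_neighbors(n_known=3, n_h=1, degree=4)
    report = guess_hydrogens(system)
    assert report.n_remaining == 0
    h = system.atoms[4].position
    assert bond_length((0, 0, 0), h) == pytest.approx(1.09, abs=1e-9)
    for k in range(1, 4):
        ang = bond_angle(system.atoms[k].position, (0, 0, 0), h)
        assert ang >= 100.0


def test_sp2_completion_is_planar_near_120():
    system = _parent_with_neighbors(n_known=2, n_h=1, degree=3)
    report = guess_hydrogens(system)
    assert report.n_remaining == 0
    h = system.atoms[3].position
    assert abs(h[2]) < 1e-9                             # in the neighbors' plane
    for k in (1, 2):
        ang = bond_angle(system.atoms[k].position, (0, 0, 0), h)
        assert ang == pytest.approx(120.0, abs=1.0)


def test_unknown_parent_leaves_hydrogen_unplaced():
    system = MolecularSystem()
    system.add_atom(Atom(segid="T", resid=1, resname="PRB", name="P0",
                         type="C", mass=12.011))
    system.add_atom(Atom(segid="T", resid=1, resname="PRB", name="H0",
                         type="H", mass=1.008))
    system.bonds = [(0, 1)]
    report = guess_hydrogens(system)
    assert ("T", 1, "H0") in report.remaining_unknown
    assert system.atoms[1].coord_status == CoordStatus.UNKNOWN


def test_methyl_hydrogens_mutually_separated(topo):
    """Three heuristic H on one sp3 parent spread at wide angles."""
    system = _parent_with_neighbors(n_known=1, n_h=3, degree=4)
    report = guess_hydrogens(system)
    assert report.n_remaining == 0
    hs = [system.atoms[i].position for i in (2, 3, 4)]
    for i in range(3):
        for j in range(i + 1, 3):
            assert bond_angle(hs[i], (0, 0, 0), hs[j]) > 60.0
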