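"""Structure generation: segments, autogeneration vs brute force, edits."""

import itertools

import numpy as np
import pytest

from mdprep.builder import (
    BuildError,
    apply_patch,
    autogenerate_angles,
    autogenerate_dihedrals,
    build_segment,
    merge_systems,
    mutate_residue,
    set_protonation,
)
from mdprep.coordinates import run_ic_guessing
from mdprep.fixtures import build_toy_peptide
from mdprep.system_model import Atom, CoordStatus, MolecularSystem

from conftest import seeded_peptide


# ---------------------------------------------------------------------------
# Independent brute-force oracles over the bond graph
# ---------------------------------------------------------------------------

def brute_force_angles(n, bonds):
    bset = {frozenset(b) for b in bonds}
    out = set()
    for i, j, k in itertools.permutations(range(n), 3):
        if i < k and frozenset((i, j)) in bset and frozenset((j, k)) in bset:
            out.add((i, j, k))
    return out


def brute_force_dihedrals(n, bonds):
    bset = {frozenset(b) for b in bonds}
    out = set()
    for quad in itertools.permutations(range(n), 4):
        i, j, k, l = quad
        if (
            frozenset((i, j)) in bset
            and frozenset((j, k)) in bset
            and frozenset((k, l)) in bset
        ):
            out.add(min(quad, quad[::-1]))
    return out


def graph_system(n, bonds):
    system = MolecularSystem()
    for i in range(n):
        system.add_atom(Atom(segid="G", resid=1, resname="GRF", name=f"A{i}", type="X"))
    system.bonds = list(bonds)
    return system


@pytest.mark.parametrize(
    "n, bonds, n_angles, n_dihedrals",
    [
        (3, [(0, 1), (0, 2)], 1, 0),          # water-like: H-O-H
        (4, [(0, 1), (1, 2), (2, 3)], 2, 1),  # chain A-B-C-D
        (5, [(0, 1), (0, 2), (0, 3), (0, 4)], 6, 0),  # 4-star: C(4,2) angles
        (3, [(0, 1), (1, 2), (2, 0)], 3, 0),  # triangle: no simple 4-path
    ],
)
def test_autogeneration_small_cases(n, bonds, n_angles, n_dihedrals):
    system = graph_system(n, bonds)
    angles = autogenerate_angles(system)
    dihedrals = autogenerate_dihedrals(system)
    assert len(angles) == n_angles
    assert len(dihedrals) == n_dihedrals
    assert set(angles) == brute_force_angles(n, bonds)
    assert set(dihedrals) == brute_force_dihedrals(n, bonds)


def test_autogeneration_matches_brute_force_on_random_graphs():
    rng = np.random.default_rng(42)
    for _ in range(60):
        n = int(rng.integers(2, 9))
        possible = list(itertools.combinations(range(n), 2))
        k = int(rng.integers(1, len(possible) + 1))
        picks = rng.choice(len(possible), size=k, replace=False)
        bonds = [possible[i] for i in picks]
        system = graph_system(n, bonds)
        assert set(autogenerate_angles(system)) == brute_force_angles(n, bonds)
        assert set(autogenerate_dihedrals(system)) == brute_force_dihedrals(n, bonds)


def test_autogeneration_is_deterministic_sorted():
    system = graph_system(4, [(2, 3), (1, 2), (0, 1)])
    angles = autogenerate_angles(system)
    assert angles == sorted(angles)
    assert autogenerate_dihedrals(system) == sorted(autogenerate_dihedrals(system))


# ---------------------------------------------------------------------------
# Segment building
# ---------------------------------------------------------------------------

def test_build_water_segment_counts(topo):
    system = MolecularSystem()
    build_segment(system, "W", [(1, "TP3W")], topo)
    assert system.n_atoms() == 3
    assert len(system.bonds) == 2
    assert len(system.angles) == 1
    assert len(system.dihedrals) == 0
    assert all(a.coord_status == CoordStatus.UNKNOWN for a in system.atoms)


def test_build_two_residue_segment_links_peptide_bond(topo):
    system = MolecularSystem()
    build_segment(system, "P", [(1, "GLY"), (2, "GLY")], topo,
                  first_patch="NONE", last_patch="NONE")
    i_c = system.find_atom("P", 1, "C")
    i_n = system.find_atom("P", 2, "N")
    assert tuple(sorted((i_c, i_n))) in system.bond_set()


def test_atoms_appended_in_template_order(topo):
    system = MolecularSystem()
    build_segment(system, "P", [(1, "GLY")], topo, first_patch="NONE", last_patch="NONE")
    assert [a.name for a in system.atoms] == ["N", "HN", "CA", "HA1", "HA2", "C", "O"]


def test_segment_charge_is_template_sum_plus_patch_deltas(topo):
    plain = MolecularSystem()
    build_segment(plain, "P", [(1, "GLY"), (2, "GLY")], topo,
                  first_patch="NONE", last_patch="NONE")
    assert plain.total_charge() == pytest.approx(0.0, abs=1e-6)

    patched = MolecularSystem()
    build_segment(patched, "P", [(1, "GLY"), (2, "GLY")], topo,
                  first_patch="NTER", last_patch="CTER")
    # NTER adds +1, CTER adds -1 on the glycine-like templates
    assert patched.total_charge() == pytest.approx(0.0, abs=1e-6)
    assert patched.segment("P").first_patch == "NTER"
    assert patched.find_atom("P", 1, "HT1") is not None
    assert patched.find_atom("P", 1, "HN") is None       # deleted by NTER
    assert patched.find_atom("P", 2, "OT2") is not None
    assert patched.find_atom("P", 2, "O") is None        # deleted by CTER


def test_unknown_residue_reports_context(topo):
    system = MolecularSystem()
    with pytest.raises(BuildError, match="P.*2"):
        build_segment(system, "P", [(1, "GLY"), (2, "XYZ")], topo)


# ---------------------------------------------------------------------------
# Patches
# ---------------------------------------------------------------------------

def test_disulfide_patch_links_and_deletes(topo):
    system = seeded_peptide(topo, ["CYS", "GLY", "CYS"])
    run_ic_guessing(system, topo)
    n_before = system.n_atoms()
    apply_patch(system, "DISU", [("P", 1), ("P", 3)], topo, regenerate=True)
    assert system.n_atoms() == n_before - 2              # two thiol H removed
    assert system.find_atom("P", 1, "HG1") is None
    i1, i3 = system.find_atom("P", 1, "SG"), system.find_atom("P", 3, "SG")
    assert tuple(sorted((i1, i3))) in system.bond_set()
    assert system.total_charge() == pytest.approx(0.0, abs=1e-6)


def test_protonation_patch_adds_one_h_and_charge(topo):
    system = seeded_peptide(topo, ["GLY", "ASP", "GLY"])
    run_ic_guessing(system, topo)
    q0 = system.total_charge()
    n0 = system.n_atoms()
    apply_patch(system, "ASPP", [("P", 2)], topo)
    assert system.n_atoms() == n0 + 1
    assert system.find_atom("P", 2, "HD2") is not None
    assert system.total_charge() == pytest.approx(q0 + 1.0, abs=1e-6)


def test_patch_regeneration_leaves_no_dangling_indices(topo):
    system = seeded_peptide(topo, ["CYS", "GLY", "CYS"])
    apply_patch(system, "DISU", [("P", 1), ("P", 3)], topo, regenerate=True)
    n = system.n_atoms()
    for terms in (system.bonds, system.angles, system.dihedrals, system.impropers):
        for term in terms:
            assert all(0 <= i < n for i in term)


def test_patch_target_count_enforced(topo):
    system = seeded_peptide(topo, ["CYS", "GLY", "CYS"])
    with pytest.raises(BuildError, match="2 residue"):
        apply_patch(system, "DISU", [("P", 1)], topo)
    with pytest.raises(BuildError):
        apply_patch(system, "NOSUCH", [("P", 1)], topo)


def test_patch_on_missing_atom_errors(topo):
    system = seeded_peptide(topo, ["GLY", "GLY"])  # GLY has no HG1 to delete
    with pytest.raises(BuildError, match="not found"):
        apply_patch(system, "DISU", [("P", 1), ("P", 2)], topo)


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

def test_mutation_preserves_shared_atom_coordinates(topo):
    system = build_toy_peptide(3, resnames=["GLY", "GLY", "GLY"], topo=topo)
    shared = ["N", "HN", "CA", "C", "O"]
    before = {
        nm: system.atoms[system.find_atom("P", 2, nm)].position.copy()
        for nm in shared
    }
    delta = mutate_residue(system, "P", 2, "ALA", topo)
    for nm in shared:
        after = system.atoms[system.find_atom("P", 2, nm)].position
        assert np.allclose(after, before[nm], atol=0.0)  # max displacement 0.0
    # glycine's HA1/HA2 replaced by alanine's HA + methyl group
    assert set(delta["added"]) == {"HA", "CB", "HB1", "HB2", "HB3"}
    for nm in delta["added"]:
        atom = system.atoms[system.find_atom("P", 2, nm)]
        assert atom.coord_status == CoordStatus.UNKNOWN
    assert delta["charge_delta"] == pytest.approx(0.0, abs=1e-6)


def test_mutation_to_same_residue_is_identity(topo):
    system = build_toy_peptide(2, resnames=["GLY", "ALA"], topo=topo)
    reference = system.copy()
    mutate_residue(system, "P", 2, "ALA", topo)
    assert system.topology_equal(reference)


def test_mutation_changes_segment_charge_by_template_difference(topo):
    system = build_toy_peptide(3, resnames=["GLY", "GLY", "GLY"], topo=topo)
    q0 = system.total_charge()
    delta = mutate_residue(system, "P", 2, "ASP", topo)
    expected = topo.residues["ASP"].charge_sum() - topo.residues["GLY"].charge_sum()
    assert delta["charge_delta"] == pytest.approx(expected, abs=1e-6)
    assert system.total_charge() == pytest.approx(q0 + expected, abs=1e-6)


def test_mutated_side_chain_is_placeable_by_ic(topo):
    system = build_toy_peptide(3, resnames=["GLY", "GLY", "GLY"], topo=topo)
    mutate_residue(system, "P", 2, "CYS", topo)
    report = run_ic_guessing(system, topo)
    assert report.n_remaining == 0
    sg = system.atoms[system.find_atom("P", 2, "SG")]
    assert sg.coord_status == CoordStatus.GUESSED


def test_mutate_missing_residue_errors(topo):
    system = build_toy_peptide(2, topo=topo)
    with pytest.raises(BuildError):
        mutate_residue(system, "P", 99, "ALA", topo)


# ---------------------------------------------------------------------------
# Protonation
# ---------------------------------------------------------------------------

def test_histidine_rename_adds_proton_and_charge(topo):
    system = build_toy_peptide(3, resnames=["GLY", "HSD", "GLY"], topo=topo)
    delta = set_protonation(system, "P", 2, "HSP", topo)
    atom = system.atoms[system.find_atom("P", 2, "HE2")]
    assert atom.coord_status == CoordStatus.UNKNOWN
    assert system.atoms[system.find_atom("P", 2, "CA")].resname == "HSP"
    assert delta["charge_delta"] == pytest.approx(1.0, abs=1e-6)


def test_asp_protonation_via_patch(topo):
    system = build_toy_peptide(3, resnames=["GLY", "ASP", "GLY"], topo=topo)
    n0 = system.n_atoms()
    delta = set_protonation(system, "P", 2, "ASPP", topo)
    assert system.n_atoms() == n0 + 1
    assert delta["charge_delta"] == pytest.approx(1.0, abs=1e-6)


def test_protonation_never_double_adds(topo):
    system = build_toy_peptide(3, resnames=["GLY", "HSD", "GLY"], topo=topo)
    set_protonation(system, "P", 2, "HSP", topo)
    n = system.n_atoms()
    result = set_protonation(system, "P", 2, "HSP", topo)  # rename: no-op
    assert result.get("noop") is True and system.n_atoms() == n

    system2 = build_toy_peptide(3, resnames=["GLY", "ASP", "GLY"], topo=topo)
    set_protonation(system2, "P", 2, "ASPP", topo)
    with pytest.raises(BuildError, match="already"):
        set_protonation(system2, "P", 2, "ASPP", topo)   # patch: explicit error


def test_unsupported_variant_lists_supported(topo):
    system = build_toy_peptide(1, topo=topo)
    with pytest.raises(BuildError, match="HSD"):
        set_protonation(system, "P", 1, "NOPE", topo)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def test_merge_systems_is_index_shifted_union(topo):
    a = build_toy_peptide(2, segid="A", topo=topo)
    b = MolecularSystem()
    build_segment(b, "W", [(1, "TP3W")], topo)
    merged = merge_systems(a, b)
    assert merged.n_atoms() == a.n_atoms() + b.n_atoms()
    assert len(merged.bonds) == len(a.bonds) + len(b.bonds)
    assert len(merged.angles) == len(a.angles) + len(b.angles)
    n = merged.n_atoms()
    assert all(0 <= i < n for term in merged.bonds for i in term)


def test_merge_with_empty_is_identity(topo):
    a = build_toy_peptide(2, segid="A", topo=topo)
    merged = merge_systems(a, MolecularSystem())
    assert merged.topology_equal(a)


def test_merge_segid_collision_errors(topo):
    a = build_toy_peptide(1, segid="A", topo=topo)
    b = build_toy_peptide(1, segid="A", topo=topo)
    with pytest.raises(BuildError, match="A"):
        merge_systems(a, b)


def test_charge_conserved_through_edit_sequence(topo):
    """Sum of atom charges always equals template sums plus patch deltas."""
    system = build_toy_peptide(4, resnames=["CYS", "ASP", "HSD", "CYS"], topo=topo)
    templates = sum(topo.residues[r].charge_sum() for r in ["CYS", "ASP", "HSD", "CYS"])
    assert system.total_charge() == pytest.approx(templates, abs=1e-6)
    set_protonation(system, "P", 2, "ASPP", topo)        # +1
    apply_patch(system, "DISU", [("P", 1), ("P", 4)], topo)  # +0
    mutate_residue(system, "P", 3, "GLY", topo)          # HSD(0) -> GLY(0)
    assert system.total_charge() == pytest.approx(templates + 1.0, abs=1e-6)
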