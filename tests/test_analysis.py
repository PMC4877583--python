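"""Superposition, RMSD/RMSF, hydrogen bonds, energy-log parsing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from mdprep.analysis import (
    count_hbonds,
    kabsch_superpose,
    parse_energy_log,
    read_trajectory_pdb,
    rmsd_series,
    rmsf_per_residue,
)
from mdprep.fixtures import make_energy_log, multimodel_pdb


def _random_rigid(rng):
    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.normal(size=3) * 5
    return rot, trans


def test_kabsch_identity_gives_zero():
    pts = np.random.default_rng(0).normal(size=(10, 3))
    rot, trans, rmsd = kabsch_superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(rot, np.eye(3), atol=1e-9)


def test_kabsch_recovers_rigid_transform():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(25, 3))
    rot, trans = _random_rigid(rng)
    moved = pts @ rot.T + trans
    r, t, rmsd = kabsch_superpose(pts, moved)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(moved @ r.T + t, pts, atol=1e-9)


def test_kabsch_two_point_hand_case():
    """Centered sets (+-0.5, 0, 0) vs (0, +-1, 0): residual 0.5 per atom."""
    reference = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    mobile = np.array([[0.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
    _, _, rmsd = kabsch_superpose(reference, mobile)
    assert rmsd == pytest.approx(0.5, abs=1e-9)


def test_kabsch_count_mismatch_raises():
    with pytest.raises(ValueError):
        kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(3, 12))
def test_kabsch_rotation_is_always_proper(seed, n):
    """det(R) = +1 even for planar/degenerate point sets (no reflections)."""
    rng = np.random.default_rng(seed)
    ref = rng.normal(size=(n, 3))
    mob = rng.normal(size=(n, 3))
    if seed % 3 == 0:
        ref[:, 2] = 0.0  # force a planar degenerate case
        mob[:, 2] = 0.0
    rot, _, _ = kabsch_superpose(ref, mob)
    assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-9)


def test_rmsd_invariant_under_common_rigid_transform():
    rng = np.random.default_rng(2)
    ref = rng.normal(size=(12, 3))
    mob = ref + rng.normal(size=(12, 3)) * 0.3
    _, _, rmsd0 = kabsch_superpose(ref, mob)
    rot, trans = _random_rigid(rng)
    _, _, rmsd1 = kabsch_superpose(ref @ rot.T + trans, mob @ rot.T + trans)
    assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)


def test_rmsd_series_static_trajectory_is_zero():
    frame = np.random.default_rng(3).normal(size=(8, 3))
    frames = np.repeat(frame[None], 5, axis=0)
    assert rmsd_series(frames) == pytest.approx(np.zeros(5), abs=1e-12)


def test_rmsd_series_alignment_semantics():
    rng = np.random.default_rng(4)
    frame = rng.normal(size=(8, 3))
    rot, trans = _random_rigid(rng)
    frames = np.stack([frame, frame @ rot.T + trans])
    aligned = rmsd_series(frames, align=True)
    raw = rmsd_series(frames, align=False)
    assert aligned[1] == pytest.approx(0.0, abs=1e-9)
    assert raw[1] > 0.1


def test_rmsd_series_single_atom_displacement():
    frames = np.zeros((3, 4, 3))
    frames[2, 1, 0] = 1.7  # atom 1 displaced by d in frame 2
    values = rmsd_series(frames, selection=[1], align=False)
    assert values == pytest.approx([0.0, 0.0, 1.7])
    with pytest.raises(ValueError, match="empty"):
        rmsd_series(frames, selection=[])


def test_rmsf_static_trajectory_is_zero():
    frame = np.random.default_rng(5).normal(size=(6, 3))
    frames = np.repeat(frame[None], 4, axis=0)
    rmsf = rmsf_per_residue(frames, residue_of_atom=[1, 1, 1, 2, 2, 2])
    assert all(v == pytest.approx(0.0, abs=1e-9) for v in rmsf.values())


def test_rmsf_two_point_alternation_gives_half_amplitude():
    """One atom alternating between x=0 and x=d fluctuates by d/2."""
    d = 1.2
    n_frames = 40
    # anchor atoms so superposition cannot absorb the motion
    frames = np.zeros((n_frames, 4, 3))
    frames[:, 1] = [10.0, 0.0, 0.0]
    frames[:, 2] = [0.0, 10.0, 0.0]
    frames[1::2, 3, 0] = d
    rmsf = rmsf_per_residue(
        frames, residue_of_atom=[1, 1, 1, 2], selection=[0, 1, 2, 3], align=False,
    )
    assert rmsf[2] == pytest.approx(d / 2.0, abs=1e-9)
    assert rmsf[1] == pytest.approx(0.0, abs=1e-9)


def test_rmsf_invariant_under_frame_permutation():
    rng = np.random.default_rng(6)
    frames = rng.normal(size=(10, 5, 3))
    res = [1, 1, 2, 2, 2]
    a = rmsf_per_residue(frames, res, align=False)
    b = rmsf_per_residue(frames[::-1].copy(), res, align=False)
    for key in a:
        assert a[key] == pytest.approx(b[key], abs=1e-12)
    with pytest.raises(ValueError, match="two frames"):
        rmsf_per_residue(frames[:1], res)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _hbond_frame(distance, angle_deg):
    """Donor D-H pointing at acceptor A with a chosen D..A distance/angle."""
    d = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    ang = np.radians(180.0 - angle_deg)
    direction = np.array([np.cos(ang), np.sin(ang), 0.0])
    a = h + direction * (distance - 1.0)
    return np.stack([d, h, a])


def test_hbond_counted_inside_criterion():
    coords = _hbond_frame(2.8, 180.0)
    n, pairs = count_hbonds(coords, donors=[(0, 1)], acceptors=[2])
    assert n == 1 and pairs == [(0, 1, 2)]


def test_hbond_distance_and_angle_cutoffs():
    too_far = _hbond_frame(4.0, 180.0)
    assert count_hbonds(too_far, [(0, 1)], [2])[0] == 0
    bent = _hbond_frame(2.8, 120.0)
    assert count_hbonds(bent, [(0, 1)], [2])[0] == 0
    assert count_hbonds(bent, [(0, 1)], [2], angle_cut=110.0)[0] == 1
    assert count_hbonds(too_far, [(0, 1)], [2], d_cut=4.5)[0] == 1


def test_hbond_no_donors_and_monotone_in_distance_cutoff():
    coords = _hbond_frame(3.0, 170.0)
    assert count_hbonds(coords, [], [2])[0] == 0
    counts = [count_hbonds(coords, [(0, 1)], [2], d_cut=d)[0]
              for d in (2.0, 3.0, 3.5, 5.0)]
    assert counts == sorted(counts)  # monotone non-decreasing in d_cut


# ---------------------------------------------------------------------------
# Energy logs
# ---------------------------------------------------------------------------

def test_energy_log_fixture_parses_to_table():
    table = parse_energy_log(make_energy_log(n_rows=3))
    assert len(table) == 3
    assert "TOTAL" in table.columns
    assert list(table["TS"]) == [0, 500, 1000]
    row = table.iloc[0]
    assert row["TOTAL"] == pytest.approx(
        row["BOND"] + row["ANGLE"] + row["DIHED"] + row["ELECT"] + row["VDW"]
    )


def test_energy_log_restart_remaps_columns():
    text = make_energy_log(n_rows=4, restart_after=2)
    table = parse_energy_log(text)
    assert len(table) == 4
    # the BOND series stays consistent across the header change
    assert list(table["BOND"]) == pytest.approx([10.0, 11.0, 12.0, 13.0])


def test_energy_log_edge_cases():
    assert parse_energy_log("").empty
    with pytest.raises(ValueError, match="ETITLE"):
        parse_energy_log("ENERGY:       0      1.0\n")


def test_trajectory_pdb_reader_and_rmsd(peptide):
    rng = np.random.default_rng(7)
    base = peptide.coordinates()
    frames = np.stack([base, base + rng.normal(size=base.shape) * 0.05])
    text = multimodel_pdb(peptide, frames)
    loaded = read_trajectory_pdb(text)
    assert loaded.shape == frames.shape
    values = rmsd_series(loaded)
    assert values[0] == pytest.approx(0.0, abs=1e-9)
    assert values[1] > 0.0
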