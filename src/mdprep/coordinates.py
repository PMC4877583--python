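"""Coordinate assignment and reconstruction of missing atoms.

Three stages take a freshly built structure from "no coordinates" to
"simulation-ready":

1. :func:`assign_coordinates` copies positions from decoded PDB records onto
   built atoms, matched by segment, residue ID and atom name (with alias
   translation for nonstandard nomenclature).
2. :func:`run_ic_guessing` reconstructs the rest from internal-coordinate
   records by fixpoint iteration: an atom is placed as soon as three of its
   IC partners have coordinates, both in the forward (place d from a,b,c)
   and the reverse (place a from d,c,b) direction.  A placement is rejected
   when it would create a bond angle below 45 degrees with the existing
   coordinates.
3. :func:`guess_hydrogens` handles hydrogens that have no IC record, using
   tetrahedral or trigonal completion around their bonded parent.

Torsion signs follow the IUPAC convention (clockwise positive looking down
the b->c axis).  All angles at this interface are degrees; lengths Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system_model import Atom, CoordStatus, MolecularSystem, PdbStructure
from .topology import AliasMap, ICRecord, TopologySet

__all__ = [
    "DegenerateFrameError",
    "AssignmentStats",
    "GuessReport",
    "MIN_BOND_ANGLE_DEG",
    "H_BOND_LENGTHS",
    "bond_length",
    "bond_angle",
    "dihedral_angle",
    "place_from_ic",
    "assign_coordinates",
    "run_ic_guessing",
    "guess_hydrogens",
]

#: Placements creating a bond angle below this (degrees) are rejected.
MIN_BOND_ANGLE_DEG = 45.0

#: Default X-H bond lengths (Angstrom) by parent element for heuristic
#: hydrogen placement.
H_BOND_LENGTHS = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}

_TETRAHEDRAL_DEG = 109.4712206344907


class DegenerateFrameError(ValueError):
    """The three frame atoms are (nearly) collinear: no torsion frame."""


# ---------------------------------------------------------------------------
# Elementary geometry
# ---------------------------------------------------------------------------

def bond_length(a, b) -> float:
    return float(np.linalg.norm(np.asarray(b, float) - np.asarray(a, float)))


def bond_angle(a, b, c) -> float:
    """Angle a-b-c at vertex b, degrees in [0, 180]."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_angle(a, b, c, d) -> float:
    """IUPAC-signed torsion a-b-c-d, degrees in (-180, 180]."""
    a, b, c, d = (np.asarray(p, float) for p in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_from_ic(a, b, c, r: float, theta: float, phi: float) -> np.ndarray:
    """Place atom d from frame atoms (a, b, c) and internal coordinates.

    The returned point satisfies ``|c-d| = r``, ``angle(b, c, d) = theta``
    and ``dihedral(a, b, c, d) = phi`` (degrees), each to 1e-6.  Raises
    :class:`DegenerateFrameError` when a, b, c are collinear (angle at b
    within ~1e-6 rad of 0 or 180 degrees), in which case the torsion is
    undefined.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc_norm = np.linalg.norm(bc)
    if bc_norm == 0.0:
        raise DegenerateFrameError("frame atoms b and c coincide")
    bc_hat = bc / bc_norm
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    ab_norm = np.linalg.norm(ab)
    if ab_norm == 0.0 or n_norm < 1e-6 * ab_norm * bc_norm:
        raise DegenerateFrameError("frame atoms a, b, c are collinear")
    n_hat = n / n_norm
    m_hat = np.cross(n_hat, bc_hat)
    th = np.radians(theta)
    ph = np.radians(phi)
    direction = (
        -np.cos(th) * bc_hat
        + np.sin(th) * np.cos(ph) * m_hat
        + np.sin(th) * np.sin(ph) * n_hat
    )
    return c + r * direction


def _perpendicular(v: np.ndarray) -> np.ndarray:
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(v)))] = 1.0
    p = np.cross(v, axis)
    return p / np.linalg.norm(p)


# ---------------------------------------------------------------------------
# Coordinate assignment from PDB records
# ---------------------------------------------------------------------------

@dataclass
class AssignmentStats:
    matched: int = 0
    unmatched_records: list = field(default_factory=list)
    still_unknown: int = 0


def assign_coordinates(
    system: MolecularSystem,
    structure: PdbStructure,
    aliases: AliasMap | None = None,
    segid_map: dict[str, str] | None = None,
) -> AssignmentStats:
    """Copy PDB record positions onto built atoms.

    Atoms are matched by (segid, resid, insertion, name); the record's
    chain ID stands in for the segment name when the PDB carries no segid
    column, optionally translated through ``segid_map``.  Atom names are
    passed through the alias table first (keyed by the record's residue
    name), so stale nomenclature still matches.  Matched atoms become
    ``known``; unmatched records are reported, never fatal.
    """
    aliases = aliases or AliasMap()
    stats = AssignmentStats()
    for rec in structure.records:
        segid = rec.segid or rec.chain
        if segid_map:
            segid = segid_map.get(segid, segid)
        name = aliases.resolve_atom_name(rec.resname, rec.name)
        idx = system.find_atom(segid, rec.resid, name, rec.insertion)
        if idx is None:
            stats.unmatched_records.append((segid, rec.resid, rec.name))
            continue
        system.atoms[idx].set_position(rec.xyz, CoordStatus.KNOWN)
        stats.matched += 1
    stats.still_unknown = sum(
        1 for a in system.atoms if a.coord_status == CoordStatus.UNKNOWN
    )
    return stats


# ---------------------------------------------------------------------------
# IC-based guessing
# ---------------------------------------------------------------------------

@dataclass
class GuessReport:
    placed: list[tuple[str, int, str]] = field(default_factory=list)
    rejected_by_angle: list[tuple[str, int, str]] = field(default_factory=list)
    heuristic: list[tuple[str, int, str]] = field(default_factory=list)
    remaining_unknown: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def n_placed(self) -> int:
        return len(self.placed)

    @property
    def n_remaining(self) -> int:
        return len(self.remaining_unknown)


def _angle_ok(system: MolecularSystem, adj, target: int, pos: np.ndarray) -> bool:
    """Check the 45-degree rule for a candidate placement of ``target``.

    Every bond angle the new atom participates in with already-placed
    atoms — both at the new atom and at each bonded neighbor — must be at
    least :data:`MIN_BOND_ANGLE_DEG`.
    """
    neigh = [
        x for x in adj.get(target, ())
        if system.atoms[x].position is not None
    ]
    for ii, x in enumerate(neigh):
        px = system.atoms[x].position
        # angles at the neighbor: target - x - z
        for z in adj.get(x, ()):
            if z == target:
                continue
            pz = system.atoms[z].position
            if pz is None:
                continue
            if bond_angle(pos, px, pz) < MIN_BOND_ANGLE_DEG:
                return False
        # angles at the placed atom: x - target - y
        for y in neigh[ii + 1:]:
            if bond_angle(px, pos, system.atoms[y].position) < MIN_BOND_ANGLE_DEG:
                return False
    return True


def _try_ic(
    system: MolecularSystem,
    adj,
    entry,
) -> tuple[int | None, np.ndarray | None, bool]:
    """Attempt one IC entry; returns (target index, position, rejected45).

    ``entry.atom_keys`` is the quadruple of (segid, resid, insertion, name)
    keys; forward placement fills atom d, reverse fills atom a.
    """
    idx = [system.find_atom(s, r, n, i) for (s, r, i, n) in entry.atom_keys]
    if any(v is None for v in idx):
        return None, None, False
    pos = [system.atoms[v].position for v in idx]
    known = [p is not None for p in pos]
    ic: ICRecord = entry.record
    ia, ib, ic_, id_ = idx

    candidates: list[tuple[int, np.ndarray]] = []
    if known[0] and known[1] and known[2] and not known[3] and ic.has_forward_values():
        # both proper and improper records place d off atom c with
        # angle(b, c, d) = theta_bcd and torsion(a, b, c, d) = phi
        try:
            p = place_from_ic(pos[0], pos[1], pos[2], ic.r_cd, ic.theta_bcd, ic.phi)
            candidates.append((id_, p))
        except DegenerateFrameError:
            pass
    elif known[3] and known[2] and known[1] and not known[0] and ic.has_reverse_values():
        try:
            if ic.improper:
                # a hangs off c; torsion(d, b, c, a) = -torsion(a, b, c, d)
                p = place_from_ic(pos[3], pos[1], pos[2], ic.r_ab, ic.theta_abc, -ic.phi)
            else:
                p = place_from_ic(pos[3], pos[2], pos[1], ic.r_ab, ic.theta_abc, ic.phi)
            candidates.append((ia, p))
        except DegenerateFrameError:
            pass

    for target, p in candidates:
        if _angle_ok(system, adj, target, p):
            return target, p, False
        return target, None, True
    return None, None, False


def run_ic_guessing(system: MolecularSystem, topo: TopologySet | None = None) -> GuessReport:
    """Fixpoint reconstruction of unknown coordinates from the IC pool.

    Sweeps the system's IC entries repeatedly until no placement succeeds
    in a full sweep or every atom has coordinates; the sweep count is
    bounded by the atom count so cyclic dependencies terminate.  Successful
    placements are marked ``guessed``; entries rejected by the 45-degree
    rule are reported.  Atoms that remain unknown are listed, never fatal.
    Already-known atoms are never touched.
    """
    report = GuessReport()
    adj = system.adjacency()
    rejected: set[tuple[str, int, str]] = set()
    max_sweeps = max(1, len(system.atoms))
    for _ in range(max_sweeps):
        progressed = False
        for entry in system.ic_pool:
            target, pos, rej = _try_ic(system, adj, entry)
            if rej and target is not None:
                atom = system.atoms[target]
                rejected.add((atom.segid, atom.resid, atom.name))
                continue
            if target is not None and pos is not None:
                atom = system.atoms[target]
                atom.set_position(pos, CoordStatus.GUESSED)
                report.placed.append((atom.segid, atom.resid, atom.name))
                rejected.discard((atom.segid, atom.resid, atom.name))
                progressed = True
        if not progressed:
            break
        if all(a.position is not None for a in system.atoms):
            break
    report.rejected_by_angle = sorted(rejected)
    report.remaining_unknown = [
        (a.segid, a.resid, a.name)
        for a in system.atoms
        if a.coord_status == CoordStatus.UNKNOWN
    ]
    return report


# ---------------------------------------------------------------------------
# Heuristic hydrogen placement
# ---------------------------------------------------------------------------

def _element_of(atom: Atom) -> str:
    m = atom.mass
    if m <= 0:
        return atom.name[:1]
    for elem, lo, hi in (
        ("H", 0.5, 3.5), ("C", 10.0, 13.5), ("N", 13.5, 15.5),
        ("O", 15.5, 18.0), ("S", 28.0, 36.0),
    ):
        if lo <= m < hi:
            return elem
    return atom.name[:1]


def _completion_directions(known: list[np.ndarray], n_needed: int, degree: int) -> list[np.ndarray]:
    """Ideal directions for missing substituents around a parent atom.

    ``known`` holds unit vectors to already-placed neighbors; ``degree`` is
    the parent's total bond count, selecting tetrahedral (4) or trigonal
    (3) completion.
    """
    out: list[np.ndarray] = []
    dirs = [d.copy() for d in known]
    for _ in range(n_needed):
        if not dirs:
            d = np.array([1.0, 0.0, 0.0])
        elif len(dirs) == 1:
            ref = _perpendicular(dirs[0])
            ang = np.radians(_TETRAHEDRAL_DEG if degree >= 4 else 120.0)
            d = np.cos(ang) * dirs[0] + np.sin(ang) * ref
        elif degree >= 4 and len(dirs) == 2:
            axis = -(dirs[0] + dirs[1])
            axis_n = np.linalg.norm(axis)
            perp = np.cross(dirs[0], dirs[1])
            perp_n = np.linalg.norm(perp)
            if axis_n < 1e-8 or perp_n < 1e-8:
                d = _perpendicular(dirs[0])
            else:
                axis /= axis_n
                perp /= perp_n
                half = np.radians(_TETRAHEDRAL_DEG / 2.0)
                d = np.cos(half) * axis + np.sin(half) * perp
        else:
            # trigonal in-plane completion, or the last tetrahedral slot:
            # opposite the sum of what is already there
            s = -np.sum(dirs, axis=0)
            s_n = np.linalg.norm(s)
            d = _perpendicular(dirs[0]) if s_n < 1e-8 else s / s_n
        d = d / np.linalg.norm(d)
        out.append(d)
        dirs.append(d)
    return out


def guess_hydrogens(system: MolecularSystem, topo: TopologySet | None = None) -> GuessReport:
    """Place IC-less hydrogens by tetrahedral / trigonal completion.

    For each unknown hydrogen whose bonded parent has coordinates, the
    parent's total bond count selects the bonding pattern (4 neighbors:
    tetrahedral, 3: trigonal planar) and the hydrogen goes into an ideal
    open slot at the per-element default bond length
    (:data:`H_BOND_LENGTHS`).  Hydrogens whose parent is itself unknown
    are left unknown and reported.
    """
    report = GuessReport()
    adj = system.adjacency()
    # group missing hydrogens by parent so multiple H's spread correctly
    by_parent: dict[int, list[int]] = {}
    for i, atom in enumerate(system.atoms):
        if atom.coord_status != CoordStatus.UNKNOWN or _element_of(atom) != "H":
            continue
        heavy = [j for j in adj.get(i, ()) if _element_of(system.atoms[j]) != "H"]
        parent = heavy[0] if heavy else (next(iter(adj.get(i, [])), None))
        if parent is None:
            report.remaining_unknown.append((atom.segid, atom.resid, atom.name))
            continue
        by_parent.setdefault(parent, []).append(i)

    for parent, hs in sorted(by_parent.items()):
        p_atom = system.atoms[parent]
        if p_atom.position is None:
            for i in hs:
                a = system.atoms[i]
                report.remaining_unknown.append((a.segid, a.resid, a.name))
            continue
        ppos = p_atom.position
        known_dirs: list[np.ndarray] = []
        for j in adj[parent]:
            q = system.atoms[j].position
            if q is not None:
                v = q - ppos
                known_dirs.append(v / np.linalg.norm(v))
        degree = len(adj[parent])
        length = H_BOND_LENGTHS.get(_element_of(p_atom), 1.0)
        dirs = _completion_directions(known_dirs, len(hs), degree)
        for i, d in zip(sorted(hs), dirs):
            a = system.atoms[i]
            a.set_position(ppos + length * d, CoordStatus.GUESSED)
            report.placed.append((a.segid, a.resid, a.name))
            report.heuristic.append((a.segid, a.resid, a.name))
    report.remaining_unknown.extend(
        (a.segid, a.resid, a.name)
        for a in system.atoms
        if a.coord_status == CoordStatus.UNKNOWN
        and (a.segid, a.resid, a.name) not in set(report.remaining_unknown)
    )
    return report
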