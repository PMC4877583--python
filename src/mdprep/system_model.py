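"""Molecular system container and PDB / PSF readers and writers.

The :class:`MolecularSystem` holds atoms in a stable 0-based order together
with all bonded-term index lists (bonds, angles, dihedrals, impropers,
cross-terms) and the segment bookkeeping a structure generator needs.

Coordinate provenance is tracked per atom (``known`` — read from a file,
``guessed`` — reconstructed from internal coordinates or heuristics,
``unknown`` — no coordinates yet) and encoded in the occupancy column of
written PDB files as 1 / 0 / -1 respectively; unknown atoms are written at
the origin.  The restraint machinery later reuses the same column
convention to fix or restrain atoms with trusted coordinates.

PSF output follows the X-PLOR/EXT dialect with the CMAP flag, which is what
NAMD consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "CoordStatus",
    "Atom",
    "Segment",
    "MolecularSystem",
    "PdbRecord",
    "PdbStructure",
    "EmptyStructureError",
    "PdbFormatError",
    "PsfFormatError",
    "read_pdb",
    "write_pdb",
    "read_psf",
    "write_psf",
]


class CoordStatus(str, Enum):
    KNOWN = "known"
    GUESSED = "guessed"
    UNKNOWN = "unknown"


class EmptyStructureError(ValueError):
    """PDB input contained no ATOM/HETATM records."""


class PdbFormatError(ValueError):
    pass


class PsfFormatError(ValueError):
    pass


@dataclass
class Atom:
    """One atom of a built system.

    ``position`` is in Angstrom or ``None`` while coordinates are unknown;
    the invariant ``coord_status == UNKNOWN  <=>  position is None`` is
    maintained through :meth:`set_position` / :meth:`clear_position`.
    """

    segid: str
    resid: int
    resname: str
    name: str
    type: str = ""
    mass: float = 0.0
    charge: float = 0.0
    insertion: str = ""
    position: np.ndarray | None = None
    coord_status: CoordStatus = CoordStatus.UNKNOWN

    def set_position(self, xyz, status: CoordStatus) -> None:
        if status == CoordStatus.UNKNOWN:
            raise ValueError("use clear_position() to mark coordinates unknown")
        p = np.asarray(xyz, dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise ValueError(f"bad position {xyz!r}")
        self.position = p
        self.coord_status = status

    def clear_position(self) -> None:
        self.position = None
        self.coord_status = CoordStatus.UNKNOWN

    def residue_key(self) -> tuple[str, int, str]:
        return (self.segid, self.resid, self.insertion)


@dataclass
class Segment:
    """A named chain of numbered residues — the unit of structure building."""

    segid: str
    residue_ids: list[tuple[int, str]] = field(default_factory=list)  # (resid, insertion)
    first_patch: str | None = None
    last_patch: str | None = None


def _norm_bond(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def _norm_angle(t: tuple[int, int, int]) -> tuple[int, int, int]:
    return t if t[0] < t[2] else (t[2], t[1], t[0])


def _norm_quad(q: tuple[int, int, int, int]) -> tuple[int, int, int, int]:
    rev = q[::-1]
    return q if q <= rev else rev


class MolecularSystem:
    """Atoms, segments and bonded-term index lists with stable indices."""

    def __init__(self) -> None:
        self.atoms: list[Atom] = []
        self.bonds: list[tuple[int, int]] = []
        self.angles: list[tuple[int, int, int]] = []
        self.dihedrals: list[tuple[int, int, int, int]] = []
        self.impropers: list[tuple[int, int, int, int]] = []
        self.cross_terms: list[tuple[int, ...]] = []
        self.segments: list[Segment] = []
        # IC pool: ICEntry objects (see builder) with fully qualified atom
        # keys; looked up by name at guessing time so later edits are seen.
        self.ic_pool: list = []
        self._index: dict[tuple[str, int, str, str], int] = {}

    # ---- bookkeeping -------------------------------------------------

    def _key(self, atom: Atom) -> tuple[str, int, str, str]:
        return (atom.segid, atom.resid, atom.insertion, atom.name)

    def rebuild_index(self) -> None:
        self._index = {self._key(a): i for i, a in enumerate(self.atoms)}

    def add_atom(self, atom: Atom) -> int:
        key = self._key(atom)
        if key in self._index:
            raise ValueError(f"duplicate atom {key}")
        self.atoms.append(atom)
        idx = len(self.atoms) - 1
        self._index[key] = idx
        return idx

    def find_atom(self, segid: str, resid: int, name: str, insertion: str = "") -> int | None:
        return self._index.get((segid, resid, insertion, name))

    def segment(self, segid: str) -> Segment:
        for s in self.segments:
            if s.segid == segid:
                return s
        raise KeyError(f"no segment {segid!r}")

    def has_segment(self, segid: str) -> bool:
        return any(s.segid == segid for s in self.segments)

    def residue_atoms(self, segid: str, resid: int, insertion: str = "") -> list[int]:
        return [
            i for i, a in enumerate(self.atoms)
            if a.segid == segid and a.resid == resid and a.insertion == insertion
        ]

    def total_charge(self) -> float:
        return sum(a.charge for a in self.atoms)

    def n_atoms(self) -> int:
        return len(self.atoms)

    # ---- bonded terms ------------------------------------------------

    def add_bond(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("self-bond")
        b = _norm_bond(i, j)
        if b not in set(map(lambda x: _norm_bond(*x), self.bonds)):
            self.bonds.append(b)

    def bond_set(self) -> set[tuple[int, int]]:
        return {_norm_bond(i, j) for i, j in self.bonds}

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(len(self.atoms))}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def remove_atoms(self, indices) -> None:
        """Delete atoms and every bonded term touching them; reindex."""
        doomed = set(indices)
        if not doomed:
            return
        remap: dict[int, int] = {}
        new_atoms: list[Atom] = []
        for i, a in enumerate(self.atoms):
            if i in doomed:
                continue
            remap[i] = len(new_atoms)
            new_atoms.append(a)
        self.atoms = new_atoms

        def keep(term):
            return all(i not in doomed for i in term)

        self.bonds = [tuple(remap[i] for i in t) for t in self.bonds if keep(t)]
        self.angles = [tuple(remap[i] for i in t) for t in self.angles if keep(t)]
        self.dihedrals = [tuple(remap[i] for i in t) for t in self.dihedrals if keep(t)]
        self.impropers = [tuple(remap[i] for i in t) for t in self.impropers if keep(t)]
        self.cross_terms = [tuple(remap[i] for i in t) for t in self.cross_terms if keep(t)]
        self.rebuild_index()
        # segments may now reference residues with no atoms; prune those ids
        live = {(a.segid, a.resid, a.insertion) for a in self.atoms}
        for seg in self.segments:
            seg.residue_ids = [
                (r, ins) for r, ins in seg.residue_ids if (seg.segid, r, ins) in live
            ]

    def coordinates(self, fill: float = 0.0) -> np.ndarray:
        """(n, 3) array; unknown atoms filled with ``fill``."""
        out = np.full((len(self.atoms), 3), fill, dtype=float)
        for i, a in enumerate(self.atoms):
            if a.position is not None:
                out[i] = a.position
        return out

    def copy(self) -> "MolecularSystem":
        out = MolecularSystem()
        out.atoms = [
            replace(a, position=None if a.position is None else a.position.copy())
            for a in self.atoms
        ]
        out.bonds = list(self.bonds)
        out.angles = list(self.angles)
        out.dihedrals = list(self.dihedrals)
        out.impropers = list(self.impropers)
        out.cross_terms = list(self.cross_terms)
        out.segments = [
            Segment(s.segid, list(s.residue_ids), s.first_patch, s.last_patch)
            for s in self.segments
        ]
        out.ic_pool = list(self.ic_pool)
        out.rebuild_index()
        return out

    def topology_equal(self, other: "MolecularSystem") -> bool:
        """Equality of atoms (identity fields) and all bonded-term sets."""
        if len(self.atoms) != len(other.atoms):
            return False
        for a, b in zip(self.atoms, other.atoms):
            if (a.segid, a.resid, a.insertion, a.resname, a.name, a.type) != (
                b.segid, b.resid, b.insertion, b.resname, b.name, b.type
            ):
                return False
            if abs(a.charge - b.charge) > 1e-6 or abs(a.mass - b.mass) > 1e-4:
                return False
        def setify(terms, norm):
            return {norm(t) for t in terms}
        return (
            setify(self.bonds, lambda t: _norm_bond(*t)) == setify(other.bonds, lambda t: _norm_bond(*t))
            and setify(self.angles, _norm_angle) == setify(other.angles, _norm_angle)
            and setify(self.dihedrals, _norm_quad) == setify(other.dihedrals, _norm_quad)
            and setify(self.impropers, _norm_quad) == setify(other.impropers, _norm_quad)
            and setify(self.cross_terms, tuple) == setify(other.cross_terms, tuple)
        )


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

@dataclass
class PdbRecord:
    """One ATOM/HETATM record, fixed-width fields decoded."""

    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resid: int
    insertion: str
    xyz: np.ndarray
    occupancy: float
    bfactor: float
    segid: str
    element: str
    hetero: bool = False


@dataclass
class PdbStructure:
    """Decoded PDB content for one model, plus file-level observations."""

    records: list[PdbRecord]
    n_models: int = 1
    model_used: int = 1
    altloc_dropped: list[tuple[str, int, str]] = field(default_factory=list)

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen


def _field(line: str, start: int, end: int) -> str:
    return line[start:end].strip() if len(line) > start else ""


def read_pdb(text: str, model: int = 1) -> PdbStructure:
    """Decode fixed-width PDB text, keeping one MODEL (default the first).

    Alternate locations are resolved by keeping the alphabetically first
    altloc of each atom; the dropped cases are listed in
    ``altloc_dropped`` so the structure check can surface them.
    Raises :class:`EmptyStructureError` when the requested model holds no
    ATOM/HETATM records, :class:`PdbFormatError` (with a line number) for
    malformed fixed-width lines.
    """
    records: list[PdbRecord] = []
    kept: dict[tuple[str, int, str, str], PdbRecord] = {}
    altloc_dropped: list[tuple[str, int, str]] = []
    n_models = 0
    current_model = 1
    in_wanted = True
    saw_model_record = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        tag = line[:6].strip().upper()
        if tag == "MODEL":
            saw_model_record = True
            n_models += 1
            try:
                current_model = int(line[6:].split()[0])
            except (ValueError, IndexError):
                current_model = n_models
            in_wanted = current_model == model
            continue
        if tag == "ENDMDL":
            in_wanted = not saw_model_record
            continue
        if tag in ("TER", "END"):
            continue
        if tag not in ("ATOM", "HETATM"):
            continue
        if not in_wanted:
            continue
        try:
            serial_s = _field(line, 6, 11)
            serial = int(serial_s, 16) if not serial_s.isdigit() and serial_s else int(serial_s)
            name = _field(line, 12, 16)
            altloc = _field(line, 16, 17)
            resname = _field(line, 17, 21)
            chain = _field(line, 21, 22)
            resid = int(_field(line, 22, 26))
            insertion = _field(line, 26, 27)
            xyz = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            occ_s = _field(line, 54, 60)
            occupancy = float(occ_s) if occ_s else 1.0
            bf_s = _field(line, 60, 66)
            bfactor = float(bf_s) if bf_s else 0.0
            segid = _field(line, 72, 76)
            element = _field(line, 76, 78)
        except (ValueError, IndexError) as exc:
            raise PdbFormatError(f"line {lineno}: malformed PDB record: {exc}") from None
        rec = PdbRecord(
            serial, name, altloc, resname, chain, resid, insertion,
            xyz, occupancy, bfactor, segid, element, hetero=tag == "HETATM",
        )
        key = (rec.chain, rec.resid, rec.insertion, rec.name)
        if key in kept:
            prev = kept[key]
            if rec.altloc and prev.altloc and rec.altloc < prev.altloc:
                records[records.index(prev)] = rec
                kept[key] = rec
            altloc_dropped.append((rec.chain, rec.resid, rec.name))
            continue
        kept[key] = rec
        records.append(rec)

    if not records:
        raise EmptyStructureError(
            f"no ATOM/HETATM records in model {model}" if saw_model_record
            else "no ATOM/HETATM records"
        )
    return PdbStructure(
        records=records,
        n_models=max(n_models, 1),
        model_used=model,
        altloc_dropped=altloc_dropped,
    )


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

_OCC_BY_STATUS = {
    CoordStatus.KNOWN: 1.0,
    CoordStatus.GUESSED: 0.0,
    CoordStatus.UNKNOWN: -1.0,
}


def _pdb_atom_name(name: str) -> str:
    # PDB convention: names of <=3 chars start in column 14
    if len(name) > 4:
        raise PdbFormatError(f"atom name {name!r} exceeds 4 characters")
    return f" {name:<3s}" if len(name) < 4 else name


def format_pdb_line(
    serial: int,
    atom: Atom,
    xyz,
    occupancy: float,
    bfactor: float,
    hex_serials: bool = False,
) -> str:
    if len(atom.resname) > 4:
        raise PdbFormatError(f"residue name {atom.resname!r} exceeds 4 characters")
    if len(atom.segid) > 4:
        raise PdbFormatError(f"segid {atom.segid!r} exceeds 4 characters")
    if atom.resid > 9999:
        raise PdbFormatError(f"resid {atom.resid} exceeds PDB field width")
    serial_s = f"{serial:5d}" if not hex_serials else f"{serial:5X}"
    chain = atom.segid[:1] if atom.segid else " "
    x, y, z = (float(v) for v in xyz)
    return (
        f"ATOM  {serial_s} {_pdb_atom_name(atom.name)} "
        f"{atom.resname:<4s}{chain}{atom.resid:4d}{atom.insertion or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{bfactor:6.2f}      "
        f"{atom.segid:<4s}"
    )


def write_pdb(system: MolecularSystem, bfactors=None) -> str:
    """Render a system as fixed-width PDB text.

    Occupancy encodes coordinate provenance (1 known / 0 guessed / -1
    unknown); unknown atoms are written at the origin.  Segment IDs go in
    columns 73-76.  Atom serials switch to hexadecimal beyond 99999 so very
    large systems stay single-file representable.  Over-wide atom/residue
    names raise rather than silently truncate.
    """
    lines: list[str] = []
    hex_serials = len(system.atoms) > 99999
    last_segid: str | None = None
    for i, atom in enumerate(system.atoms):
        if last_segid is not None and atom.segid != last_segid:
            lines.append("TER")
        last_segid = atom.segid
        xyz = atom.position if atom.position is not None else np.zeros(3)
        occ = _OCC_BY_STATUS[atom.coord_status]
        bf = 0.0 if bfactors is None else float(bfactors[i])
        lines.append(format_pdb_line(i + 1, atom, xyz, occ, bf, hex_serials))
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PSF
# ---------------------------------------------------------------------------

def write_psf(system: MolecularSystem) -> str:
    """Render X-PLOR/EXT-dialect PSF text (CMAP flag set).

    Section counts always equal the lengths of the corresponding index
    lists.  Raises :class:`PsfFormatError` naming segid:resid:name when an
    atom has no force-field type assigned.
    """
    for a in system.atoms:
        if not a.type:
            raise PsfFormatError(
                f"atom {a.segid}:{a.resid}:{a.name} has no force-field type"
            )
    out: list[str] = ["PSF EXT CMAP", ""]
    title = ["REMARKS mdprep generated structure"]
    out.append(f"{len(title):10d} !NTITLE")
    out.extend(f" {t}" for t in title)
    out.append("")
    out.append(f"{len(system.atoms):10d} !NATOM")
    for i, a in enumerate(system.atoms, start=1):
        out.append(
            f"{i:10d} {a.segid:<8s} {a.resid:<8d} {a.resname:<8s} "
            f"{a.name:<8s} {a.type:<8s} {a.charge:14.6f}{a.mass:14.6f}{0:12d}"
        )
    def section(label: str, terms, width: int, per_line: int) -> None:
        out.append("")
        out.append(f"{len(terms):10d} !{label}")
        flat = [i + 1 for t in terms for i in t]
        group = width * per_line
        for s in range(0, len(flat), group):
            out.append("".join(f"{v:10d}" for v in flat[s : s + group]))
        if not flat:
            out.append("")
    section("NBOND: bonds", system.bonds, 2, 4)
    section("NTHETA: angles", system.angles, 3, 3)
    section("NPHI: dihedrals", system.dihedrals, 4, 2)
    section("NIMPHI: impropers", system.impropers, 4, 2)
    section("NCRTERM: cross-terms", system.cross_terms, 8, 1)
    out.append("")
    return "\n".join(out) + "\n"


def read_psf(text: str) -> MolecularSystem:
    """Parse X-PLOR/EXT PSF text into a system with unknown coordinates.

    Raises :class:`PsfFormatError` when a section's declared count does not
    match the number of entries actually listed.
    """
    lines = text.splitlines()
    system = MolecularSystem()
    i = 0
    n = len(lines)

    def find_section(label: str) -> tuple[int, int]:
        for j in range(n):
            if "!" + label in lines[j]:
                return int(lines[j].split("!")[0]), j
        raise PsfFormatError(f"missing !{label} section")

    natom, j = find_section("NATOM")
    seg_order: list[str] = []
    for k in range(j + 1, j + 1 + natom):
        parts = lines[k].split()
        if len(parts) < 8:
            raise PsfFormatError(f"line {k + 1}: short atom line")
        _, segid, resid_s, resname, name, atype, charge_s, mass_s = parts[:8]
        atom = Atom(
            segid=segid, resid=int(resid_s), resname=resname, name=name,
            type=atype, charge=float(charge_s), mass=float(mass_s),
        )
        system.add_atom(atom)
        if segid not in seg_order:
            seg_order.append(segid)
    for segid in seg_order:
        seg = Segment(segid=segid)
        seen: set[tuple[int, str]] = set()
        for a in system.atoms:
            if a.segid == segid and (a.resid, a.insertion) not in seen:
                seen.add((a.resid, a.insertion))
                seg.residue_ids.append((a.resid, a.insertion))
        system.segments.append(seg)

    def read_terms(label: str, width: int):
        count, j = find_section(label)
        vals: list[int] = []
        k = j + 1
        while k < n and len(vals) < count * width:
            stripped = lines[k].strip()
            if not stripped:
                break
            try:
                vals.extend(int(v) for v in stripped.split())
            except ValueError:
                break
            k += 1
        if len(vals) != count * width:
            raise PsfFormatError(
                f"!{label}: declared {count} entries but found {len(vals) // width}"
            )
        return [tuple(v - 1 for v in vals[s : s + width]) for s in range(0, len(vals), width)]

    system.bonds = read_terms("NBOND", 2)
    system.angles = read_terms("NTHETA", 3)
    system.dihedrals = read_terms("NPHI", 4)
    system.impropers = read_terms("NIMPHI", 4)
    system.cross_terms = read_terms("NCRTERM", 8)
    return system
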