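"""CHARMM residue-topology (RTF/STR dialect) parsing and representation.

A residue topology file is the database an MD structure builder works from:
for every residue type it lists the member atoms (name, force-field type,
partial charge), the bonds between them, improper and cross-term (CMAP)
quadruples/octuples, and internal-coordinate (IC) records from which missing
Cartesian coordinates can be reconstructed.  Patches (``PRES`` blocks)
describe edits applied on top of residue templates: terminal capping,
protonation changes, disulfide cross-links.

The supported record set is the one a structure generator actually consumes:
``MASS``, ``RESI``, ``PRES``, ``ATOM``, ``BOND``/``DOUBLE``, ``IMPR``,
``CMAP``, ``IC``, ``PATCH``/``PATC``, ``DEFA``, ``DELETE``, ``AUTO``.
``GROUP`` and ``DONOR``/``ACCEPTOR`` records are recognized and ignored.
Angles and lengths are stored exactly as printed (degrees / Angstrom);
conversion to radians happens only inside geometry routines.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

__all__ = [
    "AtomTemplate",
    "ICRecord",
    "ResidueTemplate",
    "PatchTemplate",
    "AliasMap",
    "TopologySet",
    "TopologyError",
    "UnknownResidueError",
    "parse_topology",
    "merge_topologies",
    "resolve_residue",
    "serialize_topology",
]

logger = logging.getLogger(__name__)

CHARGE_TOL = 1e-6


class TopologyError(ValueError):
    """Raised for malformed or inconsistent topology input."""


class UnknownResidueError(KeyError):
    """A residue name that resolves to no template, even after aliasing."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"unknown residue type {self.name!r}"


@dataclass(frozen=True)
class AtomTemplate:
    """One atom of a residue template.

    ``charge`` is the partial charge in elementary-charge units, ``mass``
    the atomic mass in Da (filled from the MASS table when available).
    """

    name: str
    type: str
    charge: float
    mass: float = 0.0


@dataclass(frozen=True)
class ICRecord:
    """Internal-coordinate record over four atoms (a, b, c, d).

    For a *proper* record the geometry is the chain a-b-c-d: ``r_ab`` and
    ``r_cd`` are the outer bond lengths (Angstrom), ``theta_abc`` and
    ``theta_bcd`` the flanking angles (degrees) and ``phi`` the torsion
    a-b-c-d (degrees).  For an *improper* record (third atom starred in the
    file) atoms a and d are both bonded to c: ``r_ab`` is then the a-c
    distance and ``theta_abc`` the a-c-b angle, while ``phi`` is still the
    torsion of the ordered quadruple a-b-c-d.

    Atom names may carry a ``-``/``+`` prefix for the previous/next residue
    of a segment, or a ``1``/``2`` slot prefix inside two-target patches.
    Following CHARMM convention a value of 0.0 in a length or angle field
    means "unset"; a torsion of 0.0 is a legitimate value.
    """

    atom_names: tuple[str, str, str, str]
    improper: bool
    r_ab: float
    theta_abc: float
    phi: float
    theta_bcd: float
    r_cd: float

    def has_forward_values(self) -> bool:
        """True when d can be placed from (a, b, c)."""
        return self.r_cd > 0.0 and self.theta_bcd > 0.0

    def has_reverse_values(self) -> bool:
        """True when a can be placed from (b, c, d)."""
        return self.r_ab > 0.0 and self.theta_abc > 0.0


@dataclass
class ResidueTemplate:
    """A full residue description: atoms, bonded terms and IC records."""

    name: str
    atoms: list[AtomTemplate] = field(default_factory=list)
    bonds: list[tuple[str, str]] = field(default_factory=list)
    impropers: list[tuple[str, str, str, str]] = field(default_factory=list)
    cross_terms: list[tuple[str, ...]] = field(default_factory=list)
    ic_records: list[ICRecord] = field(default_factory=list)
    total_charge: float = 0.0
    default_first_patch: str | None = None
    default_last_patch: str | None = None

    def atom(self, name: str) -> AtomTemplate:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.name} has no atom {name!r}")

    def atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}

    def charge_sum(self) -> float:
        return sum(a.charge for a in self.atoms)


@dataclass
class PatchTemplate:
    """A patch (PRES): a set of edits applied to one or two residues.

    ``atoms`` entries whose name already exists in the target residue
    *modify* that atom (new type/charge, coordinates kept); new names are
    *added* with unknown coordinates.  In two-target patches atom names
    carry a leading residue-slot digit (``1``/``2``).
    """

    name: str
    atoms: list[AtomTemplate] = field(default_factory=list)
    deleted_atoms: list[str] = field(default_factory=list)
    bonds: list[tuple[str, str]] = field(default_factory=list)
    impropers: list[tuple[str, str, str, str]] = field(default_factory=list)
    ic_records: list[ICRecord] = field(default_factory=list)
    total_charge: float = 0.0

    @property
    def n_targets(self) -> int:
        """1 or 2, inferred from residue-slot prefixes on member names."""
        names: list[str] = [a.name for a in self.atoms] + list(self.deleted_atoms)
        for b in self.bonds:
            names.extend(b)
        for q in self.impropers:
            names.extend(q)
        slots = {n[0] for n in names if n[:1] in ("1", "2")}
        return 2 if "2" in slots else 1


class AliasMap:
    """Residue-name and (residue, atom)-name alias tables.

    Mirrors the ``pdbalias residue`` / ``pdbalias atom`` mechanism: names as
    they appear in an input PDB are mapped to the names the force field
    uses.  Resolution is single-step (an alias target is never itself
    re-aliased), which keeps lookups idempotent.
    """

    def __init__(self) -> None:
        self.residue: dict[str, str] = {}
        self.atom: dict[tuple[str, str], str] = {}

    def add_residue_alias(self, pdb_name: str, topo_name: str) -> None:
        self.residue[pdb_name] = topo_name

    def add_atom_alias(self, resname: str, pdb_atom: str, topo_atom: str) -> None:
        self.atom[(resname, pdb_atom)] = topo_atom

    def resolve_residue_name(self, name: str) -> str:
        return self.residue.get(name, name)

    def resolve_atom_name(self, resname: str, atom_name: str) -> str:
        return self.atom.get((resname, atom_name), atom_name)

    def copy(self) -> "AliasMap":
        out = AliasMap()
        out.residue = dict(self.residue)
        out.atom = dict(self.atom)
        return out

    def update(self, other: "AliasMap") -> None:
        self.residue.update(other.residue)
        self.atom.update(other.atom)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AliasMap)
            and self.residue == other.residue
            and self.atom == other.atom
        )


@dataclass
class TopologySet:
    """Everything parsed from one or more topology files."""

    residues: dict[str, ResidueTemplate] = field(default_factory=dict)
    patches: dict[str, PatchTemplate] = field(default_factory=dict)
    masses: dict[str, float] = field(default_factory=dict)
    aliases: AliasMap = field(default_factory=AliasMap)
    default_first_patch: str | None = None
    default_last_patch: str | None = None

    def mass_of(self, atom_type: str) -> float:
        return self.masses.get(atom_type, 0.0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TopologySet):
            return NotImplemented
        return (
            self.residues == other.residues
            and self.patches == other.patches
            and self.masses == other.masses
            and self.aliases == other.aliases
            and self.default_first_patch == other.default_first_patch
            and self.default_last_patch == other.default_last_patch
        )


_IGNORED_RECORDS = {
    "GROUP", "GROU", "DONOR", "DONO", "ACCEPTOR", "ACCE", "ANGLE", "ANGL",
    "DIHE", "THET", "END", "RETURN", "SET", "READ", "IOFORMAT", "LONEPAIR",
    "LONE", "ANISOTROPY", "ANIS",
}


def _strip_comment(line: str) -> str:
    # "!" starts a comment; "*" in column 1 is a title line
    if line.startswith("*"):
        return ""
    idx = line.find("!")
    if idx >= 0:
        line = line[:idx]
    return line.strip()


def _parse_float(tok: str, lineno: int, what: str) -> float:
    try:
        return float(tok)
    except ValueError:
        raise TopologyError(f"line {lineno}: bad {what} field {tok!r}") from None


def _finish_residue(res: ResidueTemplate) -> None:
    diff = abs(res.total_charge - res.charge_sum())
    if diff > CHARGE_TOL:
        logger.warning(
            "residue %s: declared charge %.4f differs from atom sum %.4f "
            "(keeping declared value)",
            res.name, res.total_charge, res.charge_sum(),
        )


def parse_topology(text: str) -> TopologySet:
    """Parse CHARMM-dialect residue-topology text into a :class:`TopologySet`.

    Every ``RESI`` and ``PRES`` block is captured.  The residue charge
    declared on the ``RESI`` line is retained; a mismatch against the atom
    charge sum beyond 1e-6 e produces a logged warning, not an error.
    Unknown record types are skipped with a warning.

    Raises :class:`TopologyError` for malformed ``ATOM`` lines (naming the
    line number) and for duplicate residue or patch names.
    """
    topo = TopologySet()
    current: ResidueTemplate | PatchTemplate | None = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comment(raw)
        if not line:
            continue
        tokens = line.split()
        key = tokens[0].upper()

        if key == "MASS":
            # MASS index type mass [element]
            if len(tokens) < 4:
                raise TopologyError(f"line {lineno}: MASS record needs 4 fields")
            topo.masses[tokens[2]] = _parse_float(tokens[3], lineno, "mass")
        elif key in ("RESI", "PRES"):
            if current is not None:
                if isinstance(current, ResidueTemplate):
                    _finish_residue(current)
            name = tokens[1]
            charge = _parse_float(tokens[2], lineno, "charge") if len(tokens) > 2 else 0.0
            if key == "RESI":
                if name in topo.residues:
                    raise TopologyError(f"line {lineno}: duplicate residue {name!r}")
                current = ResidueTemplate(name=name, total_charge=charge)
                topo.residues[name] = current
            else:
                if name in topo.patches:
                    raise TopologyError(f"line {lineno}: duplicate patch {name!r}")
                current = PatchTemplate(name=name, total_charge=charge)
                topo.patches[name] = current
        elif key == "ATOM":
            if current is None:
                raise TopologyError(f"line {lineno}: ATOM outside RESI/PRES block")
            if len(tokens) < 4:
                raise TopologyError(
                    f"line {lineno}: ATOM line needs name, type and charge"
                )
            name, atype = tokens[1], tokens[2]
            charge = _parse_float(tokens[3], lineno, "charge")
            mass = topo.masses.get(atype, 0.0)
            if any(a.name == name for a in current.atoms):
                raise TopologyError(
                    f"line {lineno}: duplicate atom {name!r} in {current.name}"
                )
            current.atoms.append(AtomTemplate(name, atype, charge, mass))
        elif key in ("BOND", "DOUBLE", "DOUB", "TRIPLE", "TRIP"):
            if current is None:
                raise TopologyError(f"line {lineno}: {key} outside RESI/PRES block")
            pairs = tokens[1:]
            if len(pairs) % 2:
                raise TopologyError(f"line {lineno}: odd number of bond atoms")
            for i in range(0, len(pairs), 2):
                current.bonds.append((pairs[i], pairs[i + 1]))
        elif key in ("IMPR", "IMPH"):
            if current is None:
                raise TopologyError(f"line {lineno}: IMPR outside RESI/PRES block")
            quads = tokens[1:]
            if len(quads) % 4:
                raise TopologyError(f"line {lineno}: IMPR needs multiples of 4 atoms")
            for i in range(0, len(quads), 4):
                current.impropers.append(tuple(quads[i : i + 4]))
        elif key == "CMAP":
            if current is None or not isinstance(current, ResidueTemplate):
                raise TopologyError(f"line {lineno}: CMAP outside RESI block")
            if len(tokens) != 9:
                raise TopologyError(f"line {lineno}: CMAP needs 8 atom names")
            current.cross_terms.append(tuple(tokens[1:]))
        elif key == "IC":
            if current is None:
                raise TopologyError(f"line {lineno}: IC outside RESI/PRES block")
            if len(tokens) != 10:
                raise TopologyError(f"line {lineno}: IC record needs 4 names + 5 values")
            names = tokens[1:5]
            improper = names[2].startswith("*")
            if improper:
                names[2] = names[2][1:]
            vals = [_parse_float(t, lineno, "IC value") for t in tokens[5:10]]
            current.ic_records.append(
                ICRecord(tuple(names), improper, vals[0], vals[1], vals[2], vals[3], vals[4])
            )
        elif key == "DELETE":
            if not isinstance(current, PatchTemplate):
                raise TopologyError(f"line {lineno}: DELETE outside PRES block")
            # DELETE ATOM <name> [ATOM <name> ...]
            i = 1
            while i < len(tokens):
                if tokens[i].upper() in ("ATOM", "ATOMS"):
                    i += 1
                    continue
                current.deleted_atoms.append(tokens[i])
                i += 1
        elif key in ("PATCH", "PATC"):
            if isinstance(current, ResidueTemplate):
                _apply_patch_directive(current, tokens[1:], lineno)
            else:
                logger.warning("line %d: PATCH outside RESI block skipped", lineno)
        elif key == "DEFA":
            first, last = _parse_first_last(tokens[1:], lineno)
            if first is not None:
                topo.default_first_patch = None if first.upper() == "NONE" else first
            if last is not None:
                topo.default_last_patch = None if last.upper() == "NONE" else last
        elif key == "AUTO":
            pass  # AUTO ANGLES DIHE: autogeneration is always on here
        elif key in _IGNORED_RECORDS:
            pass
        else:
            logger.warning("line %d: unknown record %r skipped", lineno, key)

    if isinstance(current, ResidueTemplate):
        _finish_residue(current)
    return topo


def _parse_first_last(tokens: list[str], lineno: int) -> tuple[str | None, str | None]:
    first = last = None
    i = 0
    while i + 1 < len(tokens) + 1 and i < len(tokens):
        kw = tokens[i].upper()
        if kw in ("FIRS", "FIRST") and i + 1 < len(tokens):
            first = tokens[i + 1]
            i += 2
        elif kw == "LAST" and i + 1 < len(tokens):
            last = tokens[i + 1]
            i += 2
        else:
            raise TopologyError(f"line {lineno}: bad FIRST/LAST directive")
    return first, last


def _apply_patch_directive(res: ResidueTemplate, tokens: list[str], lineno: int) -> None:
    first, last = _parse_first_last(tokens, lineno)
    if first is not None:
        res.default_first_patch = None if first.upper() == "NONE" else first
    if last is not None:
        res.default_last_patch = None if last.upper() == "NONE" else last


def merge_topologies(sets: list[TopologySet]) -> tuple[TopologySet, int]:
    """Merge topology sets; later sets override earlier same-name entries.

    Returns ``(merged, n_overrides)`` where ``n_overrides`` counts residue,
    patch and mass entries that were replaced.
    """
    if not sets:
        raise ValueError("merge_topologies needs at least one TopologySet")
    merged = TopologySet()
    overrides = 0
    for ts in sets:
        for name, res in ts.residues.items():
            if name in merged.residues:
                overrides += 1
            merged.residues[name] = res
        for name, pres in ts.patches.items():
            if name in merged.patches:
                overrides += 1
            merged.patches[name] = pres
        for atype, mass in ts.masses.items():
            if atype in merged.masses and merged.masses[atype] != mass:
                overrides += 1
            merged.masses[atype] = mass
        merged.aliases.update(ts.aliases)
        if ts.default_first_patch is not None:
            merged.default_first_patch = ts.default_first_patch
        if ts.default_last_patch is not None:
            merged.default_last_patch = ts.default_last_patch
    return merged, overrides


def resolve_residue(name: str, topo: TopologySet) -> ResidueTemplate:
    """Look up a residue template, applying residue-name aliases first.

    Raises :class:`UnknownResidueError` carrying the offending name when
    neither the name nor its alias target is defined; the structure-check
    report uses that to flag unknown residues.
    """
    resolved = topo.aliases.resolve_residue_name(name)
    try:
        return topo.residues[resolved]
    except KeyError:
        raise UnknownResidueError(name) from None


def _fmt_ic(ic: ICRecord) -> str:
    a, b, c, d = ic.atom_names
    cstar = ("*" + c) if ic.improper else c
    return (
        f"IC {a:<6s} {b:<6s} {cstar:<7s} {d:<6s} "
        f"{ic.r_ab:8.4f} {ic.theta_abc:8.2f} {ic.phi:9.2f} "
        f"{ic.theta_bcd:8.2f} {ic.r_cd:8.4f}"
    )


def serialize_topology(topo: TopologySet) -> str:
    """Write a TopologySet back to CHARMM-dialect text.

    ``parse_topology(serialize_topology(t)) == t`` holds for any set that
    was itself produced by :func:`parse_topology` (aliases are programmatic
    state and are not serialized).
    """
    out: list[str] = ["* residue topology written by mdprep", "*", ""]
    for atype in sorted(topo.masses):
        out.append(f"MASS  -1  {atype:<6s} {topo.masses[atype]:10.5f}")
    out.append("")
    if topo.default_first_patch or topo.default_last_patch:
        first = topo.default_first_patch or "NONE"
        last = topo.default_last_patch or "NONE"
        out.append(f"DEFA FIRS {first} LAST {last}")
    out.append("AUTO ANGLES DIHE")
    out.append("")

    def body(block: ResidueTemplate | PatchTemplate) -> None:
        for a in block.atoms:
            out.append(f"ATOM {a.name:<6s} {a.type:<6s} {a.charge:9.4f}")
        if isinstance(block, PatchTemplate):
            for name in block.deleted_atoms:
                out.append(f"DELETE ATOM {name}")
        for x, y in block.bonds:
            out.append(f"BOND {x} {y}")
        for q in block.impropers:
            out.append("IMPR " + " ".join(q))
        if isinstance(block, ResidueTemplate):
            for ct in block.cross_terms:
                out.append("CMAP " + " ".join(ct))
        for ic in block.ic_records:
            out.append(_fmt_ic(ic))
        if isinstance(block, ResidueTemplate):
            if block.default_first_patch or block.default_last_patch:
                first = block.default_first_patch or "NONE"
                last = block.default_last_patch or "NONE"
                out.append(f"PATC FIRS {first} LAST {last}")
        out.append("")

    for res in topo.residues.values():
        out.append(f"RESI {res.name:<6s} {res.total_charge:9.4f}")
        body(res)
    for pres in topo.patches.values():
        out.append(f"PRES {pres.name:<6s} {pres.total_charge:9.4f}")
        body(pres)
    out.append("END")
    return "\n".join(out) + "\n"
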