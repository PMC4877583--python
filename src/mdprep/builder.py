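"""Segment-based structure generation from residue templates.

A segment is a named, ordered chain of numbered residues.  Building one
instantiates each residue template (atoms appended in template order with
unknown coordinates), realizes intra-residue bonds plus the ``+``/``-``
inter-residue linkages, applies terminal patches, and autogenerates angles
and dihedrals from the bond graph.  Patches, point mutations and
protonation-state changes are edits on top of a built system; merging
combines independently built systems under disjoint segment names.

Angle autogeneration produces exactly the set of bonded triples
{(i, j, k) : i < k, i-j and j-k bonded}; dihedral autogeneration the set of
simple 4-paths i-j-k-l deduplicated under reversal, with no atom repeated
inside one path (so a 3-ring contributes no proper dihedral).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .system_model import Atom, CoordStatus, MolecularSystem, Segment
from .topology import (
    ICRecord,
    PatchTemplate,
    ResidueTemplate,
    TopologySet,
    resolve_residue,
)

__all__ = [
    "BuildError",
    "ICEntry",
    "build_segment",
    "autogenerate_angles",
    "autogenerate_dihedrals",
    "regenerate_angles_dihedrals",
    "apply_patch",
    "mutate_residue",
    "set_protonation",
    "merge_systems",
    "PROTONATION_VARIANTS",
]

logger = logging.getLogger(__name__)


class BuildError(ValueError):
    pass


@dataclass(frozen=True)
class ICEntry:
    """An IC record bound to concrete atoms.

    ``atom_keys`` holds four (segid, resid, insertion, name) keys; the
    ``record`` supplies geometry values and the proper/improper flag.
    """

    atom_keys: tuple[tuple[str, int, str, str], ...]
    record: ICRecord


AtomKey = tuple[str, int, str, str]


def _resolve_template_name(
    name: str,
    segid: str,
    residue_ids: list[tuple[int, str]],
    pos: int,
) -> AtomKey | None:
    """Map a template atom name (with optional -/+ prefix) to an atom key.

    Returns None when the reference walks off the end of the segment
    (terminal residues legitimately lack a -/+ neighbor).
    """
    offset = 0
    if name.startswith("-"):
        offset, name = -1, name[1:]
    elif name.startswith("+"):
        offset, name = 1, name[1:]
    target = pos + offset
    if target < 0 or target >= len(residue_ids):
        return None
    resid, insertion = residue_ids[target]
    return (segid, resid, insertion, name)


# ---------------------------------------------------------------------------
# Autogeneration
# ---------------------------------------------------------------------------

def autogenerate_angles(system: MolecularSystem) -> list[tuple[int, int, int]]:
    """All bonded triples (i, j, k), i < k, in deterministic sorted order."""
    adj = system.adjacency()
    angles: list[tuple[int, int, int]] = []
    for j in sorted(adj):
        neigh = sorted(adj[j])
        for x in range(len(neigh)):
            for y in range(x + 1, len(neigh)):
                angles.append((neigh[x], j, neigh[y]))
    return sorted(angles)


def autogenerate_dihedrals(system: MolecularSystem) -> list[tuple[int, int, int, int]]:
    """All simple bonded 4-paths i-j-k-l, deduplicated under reversal."""
    adj = system.adjacency()
    seen: set[tuple[int, int, int, int]] = set()
    out: list[tuple[int, int, int, int]] = []
    for j, k in sorted(system.bond_set()):
        for jk in ((j, k), (k, j)):
            jj, kk = jk
            for i in sorted(adj[jj] - {kk}):
                for l in sorted(adj[kk] - {jj}):
                    if i == l:
                        continue
                    quad = (i, jj, kk, l)
                    canon = min(quad, quad[::-1])
                    if canon not in seen:
                        seen.add(canon)
                        out.append(canon)
    return sorted(out)


def regenerate_angles_dihedrals(system: MolecularSystem) -> None:
    system.angles = autogenerate_angles(system)
    system.dihedrals = autogenerate_dihedrals(system)


# ---------------------------------------------------------------------------
# Segment building
# ---------------------------------------------------------------------------

def build_segment(
    system: MolecularSystem,
    segid: str,
    residues: list[tuple[int, str]],
    topo: TopologySet,
    first_patch: str | None = None,
    last_patch: str | None = None,
    regenerate: bool = True,
) -> Segment:
    """Append a new segment built from residue templates.

    ``residues`` is the ordered (resid, resname) list.  Inter-residue bonds
    declared through ``+``/``-`` references are realized between adjacent
    entries.  Terminal patches default to the residue templates' (or the
    topology-wide) FIRST/LAST declarations and may be overridden; pass
    ``"NONE"`` to suppress a default.  Angles/dihedrals are regenerated for
    the whole system afterwards unless ``regenerate`` is False.
    """
    if system.has_segment(segid):
        raise BuildError(f"segment {segid!r} already exists")
    residue_ids = [(resid, "") for resid, _ in residues]
    seg = Segment(segid=segid, residue_ids=list(residue_ids))

    templates: list[ResidueTemplate] = []
    for resid, resname in residues:
        try:
            templates.append(resolve_residue(resname, topo))
        except Exception as exc:
            raise BuildError(f"segment {segid} residue {resid}: {exc}") from exc

    for (resid, _), template in zip(residues, templates):
        for at in template.atoms:
            system.add_atom(
                Atom(
                    segid=segid, resid=resid, resname=template.name,
                    name=at.name, type=at.type, charge=at.charge,
                    mass=at.mass or topo.mass_of(at.type),
                )
            )

    # bonds (intra + inter via -/+), impropers, cross terms, IC pool
    for pos, template in enumerate(templates):
        def key_of(name: str) -> AtomKey | None:
            return _resolve_template_name(name, segid, residue_ids, pos)

        for x, y in template.bonds:
            kx, ky = key_of(x), key_of(y)
            if kx is None or ky is None:
                continue  # dangling terminal +/- reference
            ix, iy = system.find_atom(*_reorder(kx)), system.find_atom(*_reorder(ky))
            if ix is None or iy is None:
                raise BuildError(
                    f"bond {x}-{y} in {template.name} references missing atom"
                )
            system.add_bond(ix, iy)
        for quad in template.impropers:
            keys = [key_of(nm) for nm in quad]
            if any(k is None for k in keys):
                continue
            idxs = [system.find_atom(*_reorder(k)) for k in keys]
            if any(i is None for i in idxs):
                continue
            system.impropers.append(tuple(idxs))
        for octet in template.cross_terms:
            keys = [key_of(nm) for nm in octet]
            if any(k is None for k in keys):
                continue
            idxs = [system.find_atom(*_reorder(k)) for k in keys]
            if any(i is None for i in idxs):
                continue
            system.cross_terms.append(tuple(idxs))
        for ic in template.ic_records:
            keys = [key_of(nm) for nm in ic.atom_names]
            if any(k is None for k in keys):
                continue
            system.ic_pool.append(ICEntry(tuple(keys), ic))

    system.segments.append(seg)

    # terminal patches: explicit argument > per-residue PATC > topology DEFA
    def effective(explicit: str | None, template_default: str | None) -> str | None:
        if explicit is not None:
            return None if explicit.upper() == "NONE" else explicit
        return template_default

    fp = effective(first_patch, templates[0].default_first_patch or topo.default_first_patch)
    lp = effective(last_patch, templates[-1].default_last_patch or topo.default_last_patch)
    if fp:
        apply_patch(system, fp, [(segid, residues[0][0])], topo, regenerate=False)
        seg.first_patch = fp
    if lp:
        apply_patch(system, lp, [(segid, residues[-1][0])], topo, regenerate=False)
        seg.last_patch = lp

    if regenerate:
        regenerate_angles_dihedrals(system)
    return seg


def _reorder(key: AtomKey) -> tuple[str, int, str, str]:
    segid, resid, insertion, name = key
    return (segid, resid, name, insertion)


# ---------------------------------------------------------------------------
# Patching
# ---------------------------------------------------------------------------

def _patch_atom_key(name: str, targets: list[tuple[str, int]]) -> tuple[AtomKey, str]:
    """Resolve a patch atom name (optional slot digit) to an atom key."""
    slot = 0
    if name[:1] in ("1", "2") and len(targets) > 1:
        slot = int(name[0]) - 1
        name = name[1:]
    segid, resid = targets[min(slot, len(targets) - 1)]
    return (segid, resid, "", name), name


def apply_patch(
    system: MolecularSystem,
    patch_name: str,
    targets: list[tuple[str, int]],
    topo: TopologySet,
    regenerate: bool = True,
) -> None:
    """Apply a PRES patch to one or two target residues.

    Deleted atoms are removed together with every bonded term that touches
    them; patch atoms either modify an existing atom in place (type/charge
    updated, coordinates kept) or append a new atom with unknown
    coordinates.  Patch bonds, impropers and IC records are attached, the
    latter into the system's IC pool so new atoms are placeable.  With
    ``regenerate`` angles/dihedrals are rebuilt afterwards, which some
    patches require.
    """
    try:
        patch: PatchTemplate = topo.patches[patch_name]
    except KeyError:
        raise BuildError(f"unknown patch {patch_name!r}") from None
    if len(targets) != patch.n_targets:
        raise BuildError(
            f"patch {patch_name} applies to {patch.n_targets} residue(s), "
            f"got {len(targets)} target(s)"
        )

    # deletions first (CHARMM order), dropping their IC-pool references
    doomed: list[int] = []
    for raw in patch.deleted_atoms:
        key, _ = _patch_atom_key(raw, targets)
        idx = system.find_atom(*_reorder(key))
        if idx is None:
            raise BuildError(
                f"patch {patch_name}: deleted atom {raw!r} not found in target"
            )
        doomed.append(idx)
    doomed_keys = {
        (system.atoms[i].segid, system.atoms[i].resid,
         system.atoms[i].insertion, system.atoms[i].name)
        for i in doomed
    }
    system.remove_atoms(doomed)
    if doomed_keys:
        system.ic_pool = [
            e for e in system.ic_pool
            if not any(k in doomed_keys for k in e.atom_keys)
        ]

    for at in patch.atoms:
        key, bare = _patch_atom_key(at.name, targets)
        idx = system.find_atom(*_reorder(key))
        mass = at.mass or topo.mass_of(at.type)
        if idx is not None:
            atom = system.atoms[idx]
            atom.type = at.type
            atom.charge = at.charge
            atom.mass = mass
        else:
            segid, resid, insertion, _ = key
            resname = _target_resname(system, segid, resid)
            system.add_atom(
                Atom(
                    segid=segid, resid=resid, resname=resname, name=bare,
                    type=at.type, charge=at.charge, mass=mass,
                )
            )

    for x, y in patch.bonds:
        kx, _ = _patch_atom_key(x, targets)
        ky, _ = _patch_atom_key(y, targets)
        ix, iy = system.find_atom(*_reorder(kx)), system.find_atom(*_reorder(ky))
        if ix is None or iy is None:
            raise BuildError(f"patch {patch_name}: bond {x}-{y} names a missing atom")
        system.add_bond(ix, iy)
    for quad in patch.impropers:
        keys = [_patch_atom_key(nm, targets)[0] for nm in quad]
        idxs = [system.find_atom(*_reorder(k)) for k in keys]
        if any(i is None for i in idxs):
            raise BuildError(f"patch {patch_name}: improper names a missing atom")
        system.impropers.append(tuple(idxs))
    for ic in patch.ic_records:
        keys = tuple(_patch_atom_key(nm, targets)[0] for nm in ic.atom_names)
        system.ic_pool.append(ICEntry(keys, ic))

    if regenerate:
        regenerate_angles_dihedrals(system)


def _target_resname(system: MolecularSystem, segid: str, resid: int) -> str:
    for a in system.atoms:
        if a.segid == segid and a.resid == resid:
            return a.resname
    raise BuildError(f"no residue {segid}:{resid} in system")


# ---------------------------------------------------------------------------
# Mutation and protonation
# ---------------------------------------------------------------------------

def mutate_residue(
    system: MolecularSystem,
    segid: str,
    resid: int,
    new_resname: str,
    topo: TopologySet,
) -> dict:
    """Point-mutate one residue to a new template.

    Atoms whose names exist in both templates keep their coordinates (the
    backbone, typically); the rest of the old residue is removed and the
    new template's remaining atoms are added with unknown coordinates,
    pending IC guessing.  Bonded terms and the residue's IC pool are
    rebuilt; angles/dihedrals are regenerated system-wide.  Returns a small
    summary dict (kept atom names, added atom names, charge delta).
    """
    old_idx = system.residue_atoms(segid, resid)
    if not old_idx:
        raise BuildError(f"no residue {segid}:{resid} to mutate")
    old_resname = system.atoms[old_idx[0]].resname
    template = resolve_residue(new_resname, topo)
    seg = system.segment(segid)
    residue_ids = seg.residue_ids
    pos = residue_ids.index((resid, ""))

    old_charge = sum(system.atoms[i].charge for i in old_idx)
    old_names = {system.atoms[i].name for i in old_idx}
    new_names = template.atom_names()
    kept = sorted(old_names & new_names)
    removed = [i for i in old_idx if system.atoms[i].name not in new_names]

    if template.name == old_resname and not removed:
        # same template: topology unchanged by construction
        return {"kept": kept, "added": [], "charge_delta": 0.0}

    system.remove_atoms(removed)
    # drop the residue's template IC entries (patch ICs from other residues
    # survive; entries naming deleted atoms are gone either way)
    system.ic_pool = [
        e for e in system.ic_pool
        if not any(k[0] == segid and k[1] == resid for k in e.atom_keys)
        or all(system.find_atom(*_reorder(k)) is not None for k in e.atom_keys)
    ]

    added: list[str] = []
    for at in template.atoms:
        idx = system.find_atom(segid, resid, at.name)
        if idx is not None:
            atom = system.atoms[idx]
            atom.resname = template.name
            atom.type = at.type
            atom.charge = at.charge
            atom.mass = at.mass or topo.mass_of(at.type)
        else:
            system.add_atom(
                Atom(
                    segid=segid, resid=resid, resname=template.name,
                    name=at.name, type=at.type, charge=at.charge,
                    mass=at.mass or topo.mass_of(at.type),
                )
            )
            added.append(at.name)

    # rebuild this residue's bonds/impropers/ICs from the new template
    def key_of(name: str):
        return _resolve_template_name(name, segid, residue_ids, pos)

    res_atom_idx = set(system.residue_atoms(segid, resid))
    system.bonds = [
        b for b in system.bonds
        if not (b[0] in res_atom_idx and b[1] in res_atom_idx)
    ]
    for x, y in template.bonds:
        kx, ky = key_of(x), key_of(y)
        if kx is None or ky is None:
            continue
        ix, iy = system.find_atom(*_reorder(kx)), system.find_atom(*_reorder(ky))
        if ix is None or iy is None:
            continue
        system.add_bond(ix, iy)
    system.impropers = [
        q for q in system.impropers if not any(i in res_atom_idx for i in q)
    ]
    for quad in template.impropers:
        keys = [key_of(nm) for nm in quad]
        if any(k is None for k in keys):
            continue
        idxs = [system.find_atom(*_reorder(k)) for k in keys]
        if any(i is None for i in idxs):
            continue
        system.impropers.append(tuple(idxs))
    for ic in template.ic_records:
        keys = [key_of(nm) for nm in ic.atom_names]
        if any(k is None for k in keys):
            continue
        system.ic_pool.append(ICEntry(tuple(keys), ic))

    regenerate_angles_dihedrals(system)
    new_charge = sum(system.atoms[i].charge for i in system.residue_atoms(segid, resid))
    return {"kept": kept, "added": added, "charge_delta": new_charge - old_charge}


#: Supported protonation variants.  A rename entry swaps the whole residue
#: template (histidine tautomers / charged form); a patch entry applies a
#: protonation patch on top of the current residue.
PROTONATION_VARIANTS: dict[str, tuple[str, str]] = {
    "HSD": ("rename", "HSD"),
    "HSE": ("rename", "HSE"),
    "HSP": ("rename", "HSP"),
    "ASPP": ("patch", "ASPP"),
    "GLUP": ("patch", "GLUP"),
}


def set_protonation(
    system: MolecularSystem,
    segid: str,
    resid: int,
    variant: str,
    topo: TopologySet,
    table: dict[str, tuple[str, str]] | None = None,
) -> dict:
    """Switch a residue to the requested protonation state.

    Histidine-like tautomer/charged forms are template renames (handled by
    :func:`mutate_residue`, so shared atoms keep coordinates); acid
    protonations are patch applications.  Applying a variant the residue
    already has is a no-op for renames and an explicit error for patches
    (the added proton would otherwise double-add).
    """
    table = table if table is not None else PROTONATION_VARIANTS
    if variant not in table:
        raise BuildError(
            f"unsupported protonation variant {variant!r}; "
            f"supported: {sorted(table)}"
        )
    mechanism, arg = table[variant]
    atoms = system.residue_atoms(segid, resid)
    if not atoms:
        raise BuildError(f"no residue {segid}:{resid}")
    if mechanism == "rename":
        if system.atoms[atoms[0]].resname == arg:
            return {"kept": [], "added": [], "charge_delta": 0.0, "noop": True}
        return mutate_residue(system, segid, resid, arg, topo)
    patch = topo.patches.get(arg)
    if patch is None:
        raise BuildError(f"protonation patch {arg!r} missing from topology")
    existing = {system.atoms[i].name for i in atoms}
    would_add = {a.name for a in patch.atoms} - existing
    if not would_add:
        raise BuildError(
            f"residue {segid}:{resid} already carries protonation {variant}"
        )
    before = sum(system.atoms[i].charge for i in atoms)
    apply_patch(system, arg, [(segid, resid)], topo, regenerate=True)
    after = sum(
        system.atoms[i].charge for i in system.residue_atoms(segid, resid)
    )
    return {
        "kept": sorted(existing),
        "added": sorted(would_add),
        "charge_delta": after - before,
    }


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_systems(a: MolecularSystem, b: MolecularSystem) -> MolecularSystem:
    """Index-shifted union of two systems with disjoint segment names."""
    seg_a = {s.segid for s in a.segments}
    seg_b = {s.segid for s in b.segments}
    clash = seg_a & seg_b
    if clash:
        raise BuildError(f"segid collision on merge: {sorted(clash)}")
    out = a.copy()
    shift = len(out.atoms)
    bc = b.copy()
    for atom in bc.atoms:
        out.add_atom(atom)
    out.bonds += [(i + shift, j + shift) for i, j in bc.bonds]
    out.angles += [tuple(v + shift for v in t) for t in bc.angles]
    out.dihedrals += [tuple(v + shift for v in t) for t in bc.dihedrals]
    out.impropers += [tuple(v + shift for v in t) for t in bc.impropers]
    out.cross_terms += [tuple(v + shift for v in t) for t in bc.cross_terms]
    out.segments += bc.segments
    out.ic_pool += bc.ic_pool
    return out
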