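"""Cubic solvation box construction, neutralization and salt addition.

The solute is wrapped in a cubic box (edge = largest coordinate extent
plus twice the padding, centered on the solute centroid), filled by tiling
a pre-equilibrated unit water cell across the box and pruning waters that
fall outside it or come within an exclusion radius of a solute heavy atom.
Net charge is then zeroed with counterions and, when a salt concentration
is requested, Na+/Cl- pairs replace randomly chosen water molecules (the
ion takes the water oxygen's position; the replacement draw is seeded, so
ionization is bit-reproducible).

The pair count follows the water-molarity convention of common
autoionization tools: N = round(c * N_waters / 55.5), with 55.5 mol/L the
molarity of pure water.  The physiological default is 0.15 mol/L NaCl.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .system_model import Atom, CoordStatus, MolecularSystem, Segment

__all__ = [
    "Box",
    "WaterCell",
    "IonReport",
    "SolvationError",
    "compute_box",
    "solvate",
    "ionize",
    "WATER_MOLARITY",
    "DEFAULT_PADDING",
    "DEFAULT_EXCLUSION_RADIUS",
    "DEFAULT_SALT_CONCENTRATION",
]

WATER_MOLARITY = 55.5           # mol/L, pure water
DEFAULT_PADDING = 10.0          # Angstrom
DEFAULT_EXCLUSION_RADIUS = 2.4  # Angstrom
DEFAULT_SALT_CONCENTRATION = 0.15  # mol/L NaCl, physiological


class SolvationError(ValueError):
    pass


@dataclass(frozen=True)
class Box:
    """Axis-aligned cubic box: origin corner and edge length, Angstrom."""

    origin: tuple[float, float, float]
    edge: float

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.origin) + self.edge / 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        o = np.asarray(self.origin)
        return np.all((points >= o) & (points <= o + self.edge), axis=1)


@dataclass
class WaterCell:
    """A periodic unit cell of water molecules for tiling.

    ``oxygens`` is (n, 3); ``hydrogen_offsets`` (2, 3) gives the two H
    positions relative to each oxygen; ``edge`` the cell edge in Angstrom.
    """

    oxygens: np.ndarray
    hydrogen_offsets: np.ndarray
    edge: float
    resname: str = "TP3W"
    atom_names: tuple[str, str, str] = ("OH2", "H1", "H2")

    @property
    def n_waters(self) -> int:
        return len(self.oxygens)


@dataclass
class IonReport:
    n_neutralizing: int
    neutralizing_species: str
    n_salt_pairs: int
    replaced_waters: list[tuple[str, int]]
    final_charge: float


def compute_box(system: MolecularSystem, padding: float = DEFAULT_PADDING) -> Box:
    """Cubic box around the solute: extent + 2*padding, centroid-centered."""
    if any(a.position is None for a in system.atoms):
        raise SolvationError("cannot size a box: some coordinates are unknown")
    coords = system.coordinates()
    if coords.size == 0:
        raise SolvationError("empty system")
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    edge = float((hi - lo).max()) + 2.0 * padding
    center = (lo + hi) / 2.0
    origin = tuple(float(v) for v in (center - edge / 2.0))
    return Box(origin=origin, edge=edge)


def _water_segments(n: int, start: int = 1) -> list[str]:
    return [f"WT{start + i}" for i in range(n)]


def solvate(
    system: MolecularSystem,
    box: Box,
    water_cell: WaterCell,
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
    water_topology: dict | None = None,
    waters_per_segment: int = 9999,
) -> tuple[MolecularSystem, int]:
    """Fill ``box`` with tiled unit-cell water around the solute.

    Candidate waters come from replicating the unit cell over the box;
    a water is dropped when any of its atoms leaves the box or when any
    atom sits within ``exclusion_radius`` of a solute heavy atom.  Kept
    waters are appended as fresh ``WTn`` segments (at most
    ``waters_per_segment`` residues each, so PDB resid fields stay in
    range).  Returns ``(solvated_system, n_waters)``.

    ``water_topology`` may supply per-atom ``(type, charge, mass)``
    triples keyed by atom name; otherwise TIP3-like defaults are used.
    """
    solute_coords = system.coordinates()
    if solute_coords.size:
        lo, hi = solute_coords.min(axis=0), solute_coords.max(axis=0)
        if (hi - lo).max() > box.edge:
            raise SolvationError("box is smaller than the solute")

    n_cells = int(np.ceil(box.edge / water_cell.edge))
    origin = np.asarray(box.origin)
    reps = np.arange(n_cells)
    shifts = (
        np.stack(np.meshgrid(reps, reps, reps, indexing="ij"), axis=-1)
        .reshape(-1, 3) * water_cell.edge
    )
    oxygens = (shifts[:, None, :] + water_cell.oxygens[None, :, :]).reshape(-1, 3)
    oxygens = oxygens + origin

    h1 = oxygens + water_cell.hydrogen_offsets[0]
    h2 = oxygens + water_cell.hydrogen_offsets[1]
    triplets = np.stack([oxygens, h1, h2], axis=1)  # (n, 3, 3)

    inside = box.contains(triplets.reshape(-1, 3)).reshape(-1, 3).all(axis=1)
    triplets = triplets[inside]

    heavy = np.array(
        [
            a.position for a in system.atoms
            if a.position is not None and a.mass >= 3.5
        ]
    )
    if heavy.size:
        tree = cKDTree(heavy)
        dmin = tree.query(triplets.reshape(-1, 3))[0].reshape(-1, 3).min(axis=1)
        triplets = triplets[dmin >= exclusion_radius]

    out = system.copy()
    water_top = water_topology or {
        "OH2": ("OT", -0.834, 15.9994),
        "H1": ("HT", 0.417, 1.008),
        "H2": ("HT", 0.417, 1.008),
    }
    n_waters = len(triplets)
    existing_wt = sum(1 for s in out.segments if s.segid.startswith("WT"))
    seg: Segment | None = None
    for w, triple in enumerate(triplets):
        if w % waters_per_segment == 0:
            seg = Segment(segid=f"WT{existing_wt + w // waters_per_segment + 1}")
            out.segments.append(seg)
        resid = w % waters_per_segment + 1
        seg.residue_ids.append((resid, ""))
        idx = []
        for name, pos in zip(water_cell.atom_names, triple):
            atype, charge, mass = water_top[name]
            i = out.add_atom(
                Atom(
                    segid=seg.segid, resid=resid, resname=water_cell.resname,
                    name=name, type=atype, charge=charge, mass=mass,
                )
            )
            out.atoms[i].set_position(pos, CoordStatus.KNOWN)
            idx.append(i)
        o, ha, hb = idx
        out.bonds += [(o, ha), (o, hb)]
        out.angles += [(ha, o, hb)]
    return out, n_waters


def _water_residues(system: MolecularSystem, water_resname: str) -> list[tuple[str, int, list[int]]]:
    groups: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(system.atoms):
        if a.resname == water_resname:
            groups.setdefault((a.segid, a.resid), []).append(i)
    return [(seg, resid, idx) for (seg, resid), idx in sorted(groups.items())]


def ionize(
    system: MolecularSystem,
    target_concentration: float = DEFAULT_SALT_CONCENTRATION,
    rng_seed: int = 0,
    water_resname: str = "TP3W",
    ion_topology: dict | None = None,
) -> tuple[MolecularSystem, IonReport]:
    """Neutralize the system and add salt by random water replacement.

    Counterions (Na+ for a negative solute, Cl- for a positive one) first
    bring the integer net charge to zero; then ``round(c * N_waters /
    55.5)`` Na+/Cl- pairs are added.  Each ion replaces one randomly
    chosen water molecule, all three atoms, and sits on the water oxygen's
    position.  The draw uses a dedicated seeded generator, so the same
    seed reproduces the same replacement bit-for-bit.
    """
    ion_top = ion_topology or {
        "SOD": ("SOD", "SOD", 1.0, 22.98977),
        "CLA": ("CLA", "CLA", -1.0, 35.45),
    }
    waters = _water_residues(system, water_resname)
    n_waters = len(waters)

    q = system.total_charge()
    q_int = round(q)
    if abs(q - q_int) > 1e-3:
        raise SolvationError(
            f"net charge {q:.4f} is not integral; check the topology"
        )
    n_neutral = abs(q_int)
    neutral_species = "SOD" if q_int < 0 else "CLA"
    n_pairs = int(round(target_concentration * n_waters / WATER_MOLARITY))

    n_ions = n_neutral + 2 * n_pairs
    if n_ions > n_waters:
        raise SolvationError(
            f"need to replace {n_ions} waters but only {n_waters} present"
        )

    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(n_waters, size=n_ions, replace=False)

    species: list[str] = [neutral_species] * n_neutral
    for _ in range(n_pairs):
        species += ["SOD", "CLA"]

    out = system.copy()
    doomed: list[int] = []
    ion_positions: list[tuple[str, np.ndarray]] = []
    replaced: list[tuple[str, int]] = []
    for pick, sp in zip(chosen, species):
        segid, resid, idx = waters[pick]
        o_idx = min(idx)  # oxygen is the first atom of the water residue
        ion_positions.append((sp, out.atoms[o_idx].position.copy()))
        doomed.extend(idx)
        replaced.append((segid, resid))
    out.remove_atoms(doomed)

    seg_by_species = {"SOD": Segment(segid="INA"), "CLA": Segment(segid="ICL")}
    counters = {"SOD": 0, "CLA": 0}
    for sp, pos in ion_positions:
        resname, atype, charge, mass = ion_top[sp]
        counters[sp] += 1
        seg = seg_by_species[sp]
        resid = counters[sp]
        seg.residue_ids.append((resid, ""))
        i = out.add_atom(
            Atom(
                segid=seg.segid, resid=resid, resname=resname,
                name=sp, type=atype, charge=charge, mass=mass,
            )
        )
        out.atoms[i].set_position(pos, CoordStatus.KNOWN)
    for sp in ("SOD", "CLA"):
        if counters[sp]:
            out.segments.append(seg_by_species[sp])

    report = IonReport(
        n_neutralizing=n_neutral,
        neutralizing_species=neutral_species,
        n_salt_pairs=n_pairs,
        replaced_waters=replaced,
        final_charge=out.total_charge(),
    )
    return out, report
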