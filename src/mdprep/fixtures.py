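"""Self-contained synthetic inputs: a mini force field and toy structures.

Everything the test suite consumes is generated here at run time — a
CHARMM-dialect residue topology with water, a handful of amino-acid-like
residues (including a histidine tautomer trio), monovalent ions, terminal
and protonation patches and a two-target disulfide patch; extended-
conformation toy peptides; a 64-water unit cell for solvation tiling; and
NAMD-style energy-log text.

The force-field values are synthetic but physically plausible (bond
lengths ~1.0-2.0 A, angles 97-123 degrees).  Nothing downstream depends on
real CHARMM36 numerics — only on structural contracts — so the pipeline
remains usable with real topology files while the tests need no downloads.
All fixtures are pure functions of their arguments (no RNG), so derived
golden values are stable.
"""

from __future__ import annotations

import numpy as np

from .builder import build_segment
from .coordinates import run_ic_guessing
from .system_model import CoordStatus, MolecularSystem, format_pdb_line
from .solvation import WaterCell
from .topology import TopologySet, parse_topology

__all__ = [
    "make_mini_topology",
    "mini_topology_set",
    "make_toy_peptide_pdb",
    "build_toy_peptide",
    "make_water_cell",
    "make_energy_log",
    "multimodel_pdb",
]

_MINI_TOPOLOGY = """\
* synthetic mini force field for structure-generation testing
* (plausible geometry, not real CHARMM36 values)
*
MASS  -1  HT      1.00800 ! water hydrogen
MASS  -1  OT     15.99940 ! water oxygen
MASS  -1  H       1.00800 ! polar hydrogen
MASS  -1  HB      1.00800 ! aliphatic hydrogen
MASS  -1  HC      1.00800 ! charged-amine hydrogen
MASS  -1  HS      1.00800 ! thiol hydrogen
MASS  -1  NH1    14.00700 ! amide nitrogen
MASS  -1  NH3    14.00700 ! ammonium nitrogen
MASS  -1  NR1    14.00700 ! protonated ring-like nitrogen
MASS  -1  NR2    14.00700 ! bare ring-like nitrogen
MASS  -1  NR3    14.00700 ! charged ring-like nitrogen
MASS  -1  CT1    12.01100 ! aliphatic CH
MASS  -1  CT2    12.01100 ! aliphatic CH2
MASS  -1  CT3    12.01100 ! aliphatic CH3
MASS  -1  C      12.01100 ! carbonyl carbon
MASS  -1  CC     12.01100 ! carboxylate carbon
MASS  -1  CD     12.01100 ! protonated-acid carbon
MASS  -1  O      15.99940 ! carbonyl oxygen
MASS  -1  OC     15.99940 ! carboxylate oxygen
MASS  -1  OB     15.99940 ! acid carbonyl oxygen
MASS  -1  OH1    15.99940 ! hydroxyl oxygen
MASS  -1  S      32.06000 ! thiol sulfur
MASS  -1  SM     32.06000 ! disulfide sulfur
MASS  -1  SOD    22.98977 ! sodium ion
MASS  -1  CLA    35.45000 ! chloride ion

DEFA FIRS NONE LAST NONE
AUTO ANGLES DIHE

RESI TP3W    0.00 ! 3-site water
ATOM OH2  OT   -0.834
ATOM H1   HT    0.417
ATOM H2   HT    0.417
BOND OH2 H1 OH2 H2
IC -OH2 H1 OH2 H2   0.0000   0.00  127.70  104.52  0.9572

RESI GLY     0.00 ! glycine-like backbone residue
ATOM N    NH1  -0.47
ATOM HN   H     0.31
ATOM CA   CT2  -0.02
ATOM HA1  HB    0.09
ATOM HA2  HB    0.09
ATOM C    C     0.51
ATOM O    O    -0.51
BOND N HN  N CA  CA HA1  CA HA2  CA C  C O  C +N
IMPR N -C CA HN  C CA +N O
IC -C   N    CA   C     1.3300 121.00  180.00 111.00 1.5200
IC N    CA   C    +N    1.4500 111.00  180.00 116.50 1.3300
IC CA   C    +N   +CA   1.5200 116.50  180.00 121.00 1.4500
IC +N   CA   *C   O     1.3300 116.50  180.00 121.00 1.2300
IC N    CA   C    O     1.4500 111.00    0.00 121.00 1.2300
IC -C   CA   *N   HN    1.3300 121.00  180.00 114.00 1.0000
IC C    CA   N    HN    1.5200 111.00    0.00 114.00 1.0000
IC N    C    *CA  HA1   1.4500 111.00  120.00 109.00 1.0800
IC N    C    *CA  HA2   1.4500 111.00 -120.00 109.00 1.0800

RESI ALA     0.00 ! alanine-like residue
ATOM N    NH1  -0.47
ATOM HN   H     0.31
ATOM CA   CT1   0.07
ATOM HA   HB    0.09
ATOM CB   CT3  -0.27
ATOM HB1  HB    0.09
ATOM HB2  HB    0.09
ATOM HB3  HB    0.09
ATOM C    C     0.51
ATOM O    O    -0.51
BOND N HN  N CA  CA HA  CA CB  CB HB1  CB HB2  CB HB3  CA C  C O  C +N
IMPR N -C CA HN  C CA +N O
IC -C   N    CA   C     1.3300 121.00  180.00 111.00 1.5200
IC N    CA   C    +N    1.4500 111.00  180.00 116.50 1.3300
IC CA   C    +N   +CA   1.5200 116.50  180.00 121.00 1.4500
IC +N   CA   *C   O     1.3300 116.50  180.00 121.00 1.2300
IC N    CA   C    O     1.4500 111.00    0.00 121.00 1.2300
IC -C   CA   *N   HN    1.3300 121.00  180.00 114.00 1.0000
IC C    CA   N    HN    1.5200 111.00    0.00 114.00 1.0000
IC N    C    *CA  CB    1.4500 111.00  123.00 110.00 1.5400
IC N    C    *CA  HA    1.4500 111.00 -120.00 109.00 1.0800
IC N    CA   CB   HB1   1.4500 110.00  180.00 110.00 1.0800
IC HB1  CA   *CB  HB2   1.0800 110.00  120.00 110.00 1.0800
IC HB1  CA   *CB  HB3   1.0800 110.00 -120.00 110.00 1.0800

RESI CYS     0.00 ! cysteine-like residue with a free thiol
ATOM N    NH1  -0.47
ATOM HN   H     0.31
ATOM CA   CT1   0.07
ATOM HA   HB    0.09
ATOM CB   CT2  -0.11
ATOM HB1  HB    0.09
ATOM HB2  HB    0.09
ATOM SG   S    -0.23
ATOM HG1  HS    0.16
ATOM C    C     0.51
ATOM O    O    -0.51
BOND N HN  N CA  CA HA  CA CB  CB HB1  CB HB2  CB SG  SG HG1  CA C  C O  C +N
IMPR N -C CA HN  C CA +N O
IC -C   N    CA   C     1.3300 121.00  180.00 111.00 1.5200
IC N    CA   C    +N    1.4500 111.00  180.00 116.50 1.3300
IC CA   C    +N   +CA   1.5200 116.50  180.00 121.00 1.4500
IC +N   CA   *C   O     1.3300 116.50  180.00 121.00 1.2300
IC N    CA   C    O     1.4500 111.00    0.00 121.00 1.2300
IC -C   CA   *N   HN    1.3300 121.00  180.00 114.00 1.0000
IC C    CA   N    HN    1.5200 111.00    0.00 114.00 1.0000
IC N    C    *CA  CB    1.4500 111.00  123.00 110.00 1.5400
IC N    C    *CA  HA    1.4500 111.00 -120.00 109.00 1.0800
IC N    CA   CB   SG    1.4500 110.00  180.00 112.00 1.8200
IC SG   CA   *CB  HB1   1.8200 112.00  120.00 109.00 1.0800
IC SG   CA   *CB  HB2   1.8200 112.00 -120.00 109.00 1.0800
IC CA   CB   SG   HG1   1.5400 112.00  180.00  97.00 1.3400

RESI ASP     -1.00 ! aspartate-like residue (deprotonated acid)
ATOM N    NH1  -0.47
ATOM HN   H     0.31
ATOM CA   CT1   0.07
ATOM HA   HB    0.09
ATOM CB   CT2  -0.28
ATOM HB1  HB    0.09
ATOM HB2  HB    0.09
ATOM CG   CC    0.62
ATOM OD1  OC   -0.76
ATOM OD2  OC   -0.76
ATOM C    C     0.51
ATOM O    O    -0.51
BOND N HN  N CA  CA HA  CA CB  CB HB1  CB HB2  CB CG  CG OD1  CG OD2  CA C  C O  C +N
IMPR N -C CA HN  C CA +N O  OD1 CB OD2 CG
IC -C   N    CA   C     1.3300 121.00  180.00 111.00 1.5200
IC N    CA   C    +N    1.4500 111.00  180.00 116.50 1.3300
IC CA   C    +N   +CA   1.5200 116.50  180.00 121.00 1.4500
IC +N   CA   *C   O     1.3300 116.50  180.00 121.00 1.2300
IC N    CA   C    O     1.4500 111.00    0.00 121.00 1.2300
IC -C   CA   *N   HN    1.3300 121.00  180.00 114.00 1.0000
IC C    CA   N    HN    1.5200 111.00    0.00 114.00 1.0000
IC N    C    *CA  CB    1.4500 111.00  123.00 110.00 1.5400
IC N    C    *CA  HA    1.4500 111.00 -120.00 109.00 1.0800
IC N    CA   CB   CG    1.4500 110.00  180.00 113.00 1.5200
IC CG   CA   *CB  HB1   1.5200 113.00  120.00 109.00 1.0800
IC CG   CA   *CB  HB2   1.5200 113.00 -120.00 109.00 1.0800
IC CA   CB   CG   OD1   1.5400 113.00  180.00 119.00 1.2600
IC OD1  CB   *CG  OD2   1.2600 119.00  180.00 118.00 1.2600

RESI HSD     0.00 ! histidine-like, proton on the delta nitrogen
ATOM N    NH1  -0.47
ATOM HN   H     0.31
ATOM CA   CT1   0.07
ATOM HA   HB    0.09
ATOM CB   CT2  -0.18
ATOM HB1  HB    0.09
ATOM HB2  HB    0.09
ATOM ND1  NR1  -0.36
ATOM HD1  H     0.36
ATOM NE2  NR2   0.00
ATOM C    C     0.51
ATOM O    O    -0.51
BOND N HN  N CA  CA HA  CA CB  CB HB1  CB HB2  CB ND1  ND1 NE2  ND1 HD1  CA C  C O  C +N
IMPR N -C CA HN  C CA +N O
IC -C   N    CA   C     1.3300 121.00  180.00 111.00 1.5200
IC N    CA   C    +N    1.4500 111.00  180.00 116.50 1.3300
IC CA   C    +N   +CA   1.5200 116.50  180.00 121.00 1.4500
IC +N   CA   *C   O     1.3300 116.50  180.00 121.00 1.2300
IC N    CA   C    O     1.4500 111.00    0.00 121.00 1.2300
IC -C   CA   *N   HN    1.3300 121.00  180.00 114.00 1.0000
IC C    CA   N    HN    1.5200 111.00    0.00 114.00 1.0000
IC N    C    *CA  CB    1.4500 111.00  123.00 110.00 1.5400
IC N    C    *CA  HA    1.4500 111.00 -120.00 109.00 1.0800
IC N    CA   CB   ND1   1.4500 110.00  180.00 112.00 1.4800
IC ND1  CA   *CB  HB1   1.4800 112.00  120.00 109.00 1.0800
IC ND1  CA   *CB  HB2   1.4800 112.00 -120.00 109.00 1.0800
IC CA   CB   ND1  NE2   1.5400 112.00  180.00 118.00 1.4000
IC NE2  CB   *ND1 HD1   1.4000 118.00  180.00 119.00 1.0000

RESI HSE     0.00 ! histidine-like, proton on the epsilon nitrogen
ATOM N    NH1  -0.47
ATOM HN   H     0.31
ATOM CA   CT1   0.07
ATOM HA   HB    0.09
ATOM CB   CT2  -0.18
ATOM HB1  HB    0.09
ATOM HB2  HB    0.09
ATOM ND1  NR2   0.00
ATOM NE2  NR1  -0.36
ATOM HE2  H     0.36
ATOM C    C     0.51
ATOM O    O    -0.51
BOND N HN  N CA  CA HA  CA CB  CB HB1  CB HB2  CB ND1  ND1 NE2  NE2 HE2  CA C  C O  C +N
IMPR N -C CA HN  C CA +N O
IC -C   N    CA   C     1.3300 121.00  180.00 111.00 1.5200
IC N    CA   C    +N    1.4500 111.00  180.00 116.50 1.3300
IC CA   C    +N   +CA   1.5200 116.50  180.00 121.00 1.4500
IC +N   CA   *C   O     1.3300 116.50  180.00 121.00 1.2300
IC N    CA   C    O     1.4500 111.00    0.00 121.00 1.2300
IC -C   CA   *N   HN    1.3300 121.00  180.00 114.00 1.0000
IC C    CA   N    HN    1.5200 111.00    0.00 114.00 1.0000
IC N    C    *CA  CB    1.4500 111.00  123.00 110.00 1.5400
IC N    C    *CA  HA    1.4500 111.00 -120.00 109.00 1.0800
IC N    CA   CB   ND1   1.4500 110.00  180.00 112.00 1.4800
IC ND1  CA   *CB  HB1   1.4800 112.00  120.00 109.00 1.0800
IC ND1  CA   *CB  HB2   1.4800 112.00 -120.00 109.00 1.0800
IC CA   CB   ND1  NE2   1.5400 112.00  180.00 118.00 1.4000
IC CB   ND1  NE2  HE2   1.4800 118.00  180.00 110.00 1.0000

RESI HSP     1.00 ! histidine-like, doubly protonated (+1)
ATOM N    NH1  -0.47
ATOM HN   H     0.31
ATOM CA   CT1   0.07
ATOM HA   HB    0.09
ATOM CB   CT2   0.04
ATOM HB1  HB    0.09
ATOM HB2  HB    0.09
ATOM ND1  NR3  -0.05
ATOM HD1  H     0.44
ATOM NE2  NR3  -0.05
ATOM HE2  H     0.44
ATOM C    C     0.51
ATOM O    O    -0.51
BOND N HN  N CA  CA HA  CA CB  CB HB1  CB HB2  CB ND1  ND1 NE2  ND1 HD1  NE2 HE2  CA C  C O  C +N
IMPR N -C CA HN  C CA +N O
IC -C   N    CA   C     1.3300 121.00  180.00 111.00 1.5200
IC N    CA   C    +N    1.4500 111.00  180.00 116.50 1.3300
IC CA   C    +N   +CA   1.5200 116.50  180.00 121.00 1.4500
IC +N   CA   *C   O     1.3300 116.50  180.00 121.00 1.2300
IC N    CA   C    O     1.4500 111.00    0.00 121.00 1.2300
IC -C   CA   *N   HN    1.3300 121.00  180.00 114.00 1.0000
IC C    CA   N    HN    1.5200 111.00    0.00 114.00 1.0000
IC N    C    *CA  CB    1.4500 111.00  123.00 110.00 1.5400
IC N    C    *CA  HA    1.4500 111.00 -120.00 109.00 1.0800
IC N    CA   CB   ND1   1.4500 110.00  180.00 112.00 1.4800
IC ND1  CA   *CB  HB1   1.4800 112.00  120.00 109.00 1.0800
IC ND1  CA   *CB  HB2   1.4800 112.00 -120.00 109.00 1.0800
IC CA   CB   ND1  NE2   1.5400 112.00  180.00 118.00 1.4000
IC NE2  CB   *ND1 HD1   1.4000 118.00  180.00 119.00 1.0000
IC CB   ND1  NE2  HE2   1.4800 118.00  180.00 110.00 1.0000

RESI SOD     1.00 ! sodium counterion
ATOM SOD  SOD   1.00

RESI CLA    -1.00 ! chloride counterion
ATOM CLA  CLA  -1.00

PRES NTER    1.00 ! protonated amino terminus
DELETE ATOM HN
ATOM N    NH3  -0.30
ATOM HT1  HC    0.33
ATOM HT2  HC    0.33
ATOM HT3  HC    0.33
ATOM CA   CT2   0.13
BOND N HT1  N HT2  N HT3
IC C    CA   N    HT1   1.5200 111.00  180.00 110.00 1.0400
IC HT1  CA   *N   HT2   1.0400 110.00  120.00 110.00 1.0400
IC HT1  CA   *N   HT3   1.0400 110.00 -120.00 110.00 1.0400

PRES CTER   -1.00 ! carboxylate carboxy terminus
DELETE ATOM O
ATOM C    CC    0.34
ATOM OT1  OC   -0.67
ATOM OT2  OC   -0.67
BOND C OT1  C OT2
IC N    CA   C    OT1   1.4500 111.00    0.00 118.00 1.2600
IC OT1  CA   *C   OT2   1.2600 118.00  180.00 118.00 1.2600

PRES ASPP    1.00 ! protonate the aspartate-like side chain (adds HD2)
ATOM CG   CD    0.75
ATOM OD1  OB   -0.48
ATOM OD2  OH1  -0.61
ATOM HD2  H     0.44
BOND OD2 HD2
IC CB   CG   OD2  HD2   1.5200 115.00  180.00 105.00 0.9600

PRES DISU    0.00 ! disulfide cross-link between two cysteine-like residues
DELETE ATOM 1HG1
DELETE ATOM 2HG1
ATOM 1CB  CT2  -0.10
ATOM 1SG  SM   -0.08
ATOM 2CB  CT2  -0.10
ATOM 2SG  SM   -0.08
BOND 1SG 2SG
IC 1CA  1CB  1SG  2SG   1.5400 112.00  180.00 103.00 2.0200
IC 1CB  1SG  2SG  2CB   1.8200 103.00   90.00 103.00 1.8200

END
"""


def make_mini_topology() -> str:
    """CHARMM-dialect text of the synthetic mini force field."""
    return _MINI_TOPOLOGY


def mini_topology_set() -> TopologySet:
    """Parsed mini force field with the standard water alias registered."""
    topo = parse_topology(make_mini_topology())
    topo.aliases.add_residue_alias("HOH", "TP3W")
    topo.aliases.add_residue_alias("TIP3", "TP3W")
    topo.aliases.add_atom_alias("HOH", "O", "OH2")
    return topo


# ---------------------------------------------------------------------------
# Toy peptide
# ---------------------------------------------------------------------------

def build_toy_peptide(
    n_res: int,
    resnames: list[str] | None = None,
    segid: str = "P",
    topo: TopologySet | None = None,
    first_patch: str = "NONE",
    last_patch: str = "NONE",
) -> MolecularSystem:
    """Fully coordinated extended-conformation peptide built from templates.

    The first three backbone atoms are seeded by hand; everything else,
    hydrogens included, comes from the residues' IC records, so the
    result is deterministic.
    """
    if n_res < 1:
        raise ValueError("need at least one residue")
    topo = topo or mini_topology_set()
    resnames = list(resnames) if resnames else ["GLY"] * n_res
    if len(resnames) != n_res:
        raise ValueError("resnames length must equal n_res")
    system = MolecularSystem()
    build_segment(
        system, segid, [(i + 1, rn) for i, rn in enumerate(resnames)], topo,
        first_patch=first_patch, last_patch=last_patch,
    )
    # seed the first backbone frame: N and CA on x, C in the xy-plane at
    # the template N-CA-C angle of 111 degrees
    i_n = system.find_atom(segid, 1, "N")
    i_ca = system.find_atom(segid, 1, "CA")
    i_c = system.find_atom(segid, 1, "C")
    system.atoms[i_n].set_position((0.0, 0.0, 0.0), CoordStatus.KNOWN)
    system.atoms[i_ca].set_position((1.45, 0.0, 0.0), CoordStatus.KNOWN)
    ang = np.radians(180.0 - 111.0)
    system.atoms[i_c].set_position(
        (1.45 + 1.52 * np.cos(ang), 1.52 * np.sin(ang), 0.0), CoordStatus.KNOWN
    )
    run_ic_guessing(system, topo)
    return system


def make_toy_peptide_pdb(
    n_res: int,
    missing: set[str] | None = None,
    gap_after: int | None = None,
    resnames: list[str] | None = None,
    chain: str = "P",
    segid: str = "P",
) -> str:
    """Deterministic extended-peptide PDB text (heavy atoms only).

    ``missing`` names are omitted from every residue, emulating atoms
    absent from a crystal structure; ``gap_after`` shifts the numbering of
    later residues by +2, creating an interior sequence gap.  Hydrogens
    are never written, as in typical X-ray input.
    """
    missing = missing or set()
    system = build_toy_peptide(n_res, resnames=resnames, segid=segid)
    lines: list[str] = []
    serial = 0
    for atom in system.atoms:
        if atom.mass < 3.5:          # crystal files rarely resolve hydrogens
            continue
        if atom.name in missing:
            continue
        resid = atom.resid + (2 if gap_after is not None and atom.resid > gap_after else 0)
        serial += 1
        shown = type(atom)(
            segid=chain, resid=resid, resname=atom.resname, name=atom.name,
            insertion=atom.insertion,
        )
        lines.append(
            format_pdb_line(serial, shown, atom.position, occupancy=1.0, bfactor=0.0)
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Water cell, logs, trajectories
# ---------------------------------------------------------------------------

def make_water_cell() -> WaterCell:
    """64 waters on a 4x4x4 lattice in a 9.3 A cubic cell.

    Oxygen spacing is 9.3/4 = 2.325 A; all molecules share one
    orientation, with both hydrogens inside the cell bounds so tiling the
    cell never pokes atoms outside a whole number of cells.
    """
    edge = 9.3
    spacing = edge / 4.0
    pts = (np.arange(4) + 0.5) * spacing
    oxygens = np.stack(np.meshgrid(pts, pts, pts, indexing="ij"), axis=-1).reshape(-1, 3)
    r_oh = 0.9572
    half = np.radians(104.52 / 2.0)
    offsets = np.array(
        [
            [r_oh * np.sin(half), 0.0, r_oh * np.cos(half)],
            [-r_oh * np.sin(half), 0.0, r_oh * np.cos(half)],
        ]
    )
    return WaterCell(oxygens=oxygens, hydrogen_offsets=offsets, edge=edge)


def make_energy_log(n_rows: int = 3, restart_after: int | None = None) -> str:
    """NAMD-style ETITLE:/ENERGY: text with deterministic values.

    With ``restart_after`` a second ETITLE header (columns reordered, as a
    restarted engine might print) appears after that many rows.
    """
    cols = ["TS", "BOND", "ANGLE", "DIHED", "ELECT", "VDW", "TOTAL", "TEMP"]
    cols2 = ["TS", "ELECT", "VDW", "BOND", "ANGLE", "DIHED", "TOTAL", "TEMP"]
    out = ["ETITLE:    " + "".join(f"{c:>15s}" for c in cols)]
    header = cols
    for i in range(n_rows):
        if restart_after is not None and i == restart_after:
            header = cols2
            out.append("ETITLE:    " + "".join(f"{c:>15s}" for c in cols2))
        step = i * 500
        base = {
            "TS": step,
            "BOND": 10.0 + i,
            "ANGLE": 20.0 + i,
            "DIHED": 5.0 + i,
            "ELECT": -1200.0 - i,
            "VDW": -80.0 + 0.5 * i,
            "TEMP": 300.0 + 0.1 * i,
        }
        base["TOTAL"] = base["BOND"] + base["ANGLE"] + base["DIHED"] + base["ELECT"] + base["VDW"]
        out.append(
            "ENERGY:    "
            + "".join(
                f"{base[c]:15d}" if c == "TS" else f"{base[c]:15.4f}" for c in header
            )
        )
    return "\n".join(out) + "\n"


def multimodel_pdb(system: MolecularSystem, frames: np.ndarray) -> str:
    """Render (n_frames, n_atoms, 3) coordinates as a multi-MODEL PDB."""
    frames = np.asarray(frames, dtype=float)
    out: list[str] = []
    for m in range(frames.shape[0]):
        out.append(f"MODEL     {m + 1:4d}")
        for i, atom in enumerate(system.atoms):
            out.append(
                format_pdb_line(i + 1, atom, frames[m, i], occupancy=1.0, bfactor=0.0)
            )
        out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"
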