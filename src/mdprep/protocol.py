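"""Simulation-protocol generation: NAMD-style configuration documents.

The environment (vacuum, implicit solvent, explicit solvent, membrane)
fixes how electrostatics and boundaries are treated:

======================  =============  ==============  =============
environment             periodic cell  electrostatics  constant area
======================  =============  ==============  =============
vacuum                  off            cut-off (eps=80)  n/a
implicit                off            GBIS            n/a
explicit                on             PME             n/a
membrane                on             PME             optional
======================  =============  ==============  =============

The default protocol is the standard four-stage ramp: energy minimization,
temperature annealing with a restrained backbone, restrained equilibration,
then free production.  Annealing plus equilibration together span 1 ns at
the 2 fs timestep (500,000 steps), so systems reach the target temperature
slowly before production.  Nonbonded handling follows common explicit-
solvent practice: 12.0 A cutoff with switching from 10.0 A, PME for
long-range electrostatics, and the r-RESPA multiple-timestep integrator
evaluating long-range forces every second step.

Each stage compiles to one plain-text configuration file of ``key value``
lines; restrained stages reference a PDB whose B-factor column carries the
per-atom force constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .system_model import MolecularSystem, write_pdb

__all__ = [
    "EnvironmentSpec",
    "ProtocolStage",
    "SMDSpec",
    "ConfigDocument",
    "ProtocolError",
    "default_protocol",
    "generate_config",
    "write_restraint_reference",
    "setup_smd",
    "parse_config_text",
    "select_atoms",
    "BACKBONE_NAMES",
    "DEFAULTS",
]

logger = logging.getLogger(__name__)

#: Tunable protocol defaults (all overridable per call, all logged into the
#: session record so runs are self-describing).
DEFAULTS = {
    "target_temperature": 300.0,      # K
    "annealing_start_temperature": 60.0,  # K
    "annealing_increment": 25.0,      # K per reassignment
    "restraint_k": 2.0,               # kcal/mol/A^2 on the backbone
    "timestep": 2.0,                  # fs
    "cutoff": 12.0,                   # A
    "switch_dist": 10.0,              # A
    "pairlist_dist": 13.5,            # A
    "pme_grid_spacing": 1.0,          # A
    "langevin_damping": 1.0,          # 1/ps
    "pressure_atm": 1.0,              # Langevin piston target
    "dielectric_vacuum": 80.0,
    "minimize_steps": 1000,
    "equilibration_ns": 1.0,          # annealing + equilibration span
    "production_steps": 500000,
    "smd_spring_k": 7.0,              # kcal/mol/A^2
}

BACKBONE_NAMES = ("N", "CA", "C", "O")


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class EnvironmentSpec:
    """Simulation environment; box edges required for periodic kinds."""

    kind: str                       # vacuum | implicit | explicit | membrane
    box: tuple[float, float, float] | None = None
    salt: float = 0.0               # mol/L
    constant_area: bool = False
    box_center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("vacuum", "implicit", "explicit", "membrane"):
            raise ProtocolError(f"unknown environment kind {self.kind!r}")
        if self.periodic and self.box is None:
            raise ProtocolError(f"{self.kind} environment requires a box")
        if self.constant_area and self.kind != "membrane":
            raise ProtocolError("constant_area is a membrane-only option")

    @property
    def periodic(self) -> bool:
        return self.kind in ("explicit", "membrane")


@dataclass(frozen=True)
class SMDSpec:
    """Constant-velocity pulling: spring on the pull group, fixed anchor."""

    velocity: float                 # A/ns, set by the user (no default)
    spring_k: float                 # kcal/mol/A^2
    anchor_selection: str
    pull_selection: str
    direction: tuple[float, float, float]


@dataclass(frozen=True)
class ProtocolStage:
    kind: str                       # minimization | annealing | equilibration | production | smd
    name: str
    steps: int
    temperature_start: float
    temperature_end: float
    restrained_selection: str | None = None
    restraint_k: float = 0.0
    smd: SMDSpec | None = None

    def __post_init__(self) -> None:
        if self.steps <= 0:
            raise ProtocolError("stage steps must be positive")
        if (self.smd is not None) != (self.kind == "smd"):
            raise ProtocolError("smd parameters present iff kind == 'smd'")
        if self.kind != "annealing" and self.temperature_start != self.temperature_end:
            raise ProtocolError("only annealing stages may ramp temperature")

    @property
    def restrained(self) -> bool:
        return self.restrained_selection is not None and self.restraint_k > 0


@dataclass
class ConfigDocument:
    """Ordered key/value parameters plus the file names they reference."""

    stage_name: str
    entries: list[tuple[str, str]] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)

    def set(self, key: str, value) -> None:
        self.entries.append((key, _fmt(value)))

    def get(self, key: str) -> str | None:
        for k, v in self.entries:
            if k.lower() == key.lower():
                return v
        return None

    def has(self, key: str) -> bool:
        return self.get(key) is not None

    def to_text(self) -> str:
        lines = [f"# stage: {self.stage_name}"]
        width = max((len(k) for k, _ in self.entries), default=0)
        for k, v in self.entries:
            lines.append(f"{k:<{width}s}  {v}")
        return "\n".join(lines) + "\n"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ConfigDocument)
            and self.stage_name == other.stage_name
            and self.entries == other.entries
        )


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "on" if value else "off"
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def parse_config_text(text: str) -> ConfigDocument:
    """Parse ``key value`` config text back into a ConfigDocument."""
    stage = ""
    entries: list[tuple[str, str]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("# stage:"):
                stage = line.split(":", 1)[1].strip()
            continue
        parts = line.split(None, 1)
        entries.append((parts[0], parts[1].strip() if len(parts) > 1 else ""))
    return ConfigDocument(stage_name=stage, entries=entries)


# ---------------------------------------------------------------------------
# Default protocol
# ---------------------------------------------------------------------------

def default_protocol(
    environment: EnvironmentSpec,
    target_temperature: float | None = None,
    overrides: dict | None = None,
) -> list[ProtocolStage]:
    """The standard minimization/annealing/equilibration/production ladder.

    Annealing ramps from a low start temperature to the target with the
    backbone restrained; annealing plus equilibration together cover 1 ns
    at the 2 fs timestep (500,000 steps), split 1:3.
    """
    p = dict(DEFAULTS)
    if overrides:
        p.update(overrides)
    t_end = float(target_temperature if target_temperature is not None
                  else p["target_temperature"])
    total_equil = int(round(p["equilibration_ns"] * 1e6 / p["timestep"]))
    anneal_steps = total_equil // 4
    equil_steps = total_equil - anneal_steps
    return [
        ProtocolStage(
            kind="minimization", name="min", steps=int(p["minimize_steps"]),
            temperature_start=0.0, temperature_end=0.0,
            restrained_selection="backbone", restraint_k=p["restraint_k"],
        ),
        ProtocolStage(
            kind="annealing", name="annealing", steps=anneal_steps,
            temperature_start=float(p["annealing_start_temperature"]),
            temperature_end=t_end,
            restrained_selection="backbone", restraint_k=p["restraint_k"],
        ),
        ProtocolStage(
            kind="equilibration", name="equilibration", steps=equil_steps,
            temperature_start=t_end, temperature_end=t_end,
            restrained_selection="backbone", restraint_k=p["restraint_k"],
        ),
        ProtocolStage(
            kind="production", name="production", steps=int(p["production_steps"]),
            temperature_start=t_end, temperature_end=t_end,
        ),
    ]


# ---------------------------------------------------------------------------
# Config generation
# ---------------------------------------------------------------------------

def generate_config(
    stage: ProtocolStage,
    environment: EnvironmentSpec,
    files: dict[str, str],
    previous_stage: ProtocolStage | None = None,
    overrides: dict | None = None,
) -> ConfigDocument:
    """Compile one stage + environment into a configuration document.

    ``files`` must provide ``structure`` (PSF) and ``coordinates`` (PDB);
    restrained stages additionally need ``restraints`` (the reference PDB
    whose B-factor column holds force constants) and SMD stages ``smdfile``.
    When a previous stage is given, its output prefix feeds this stage's
    input velocities/coordinates so the ladder chains.
    """
    p = dict(DEFAULTS)
    if overrides:
        p.update(overrides)
    doc = ConfigDocument(stage_name=stage.name)
    doc.files = dict(files)

    doc.set("structure", files["structure"])
    doc.set("coordinates", files["coordinates"])
    doc.set("outputName", files.get("output", stage.name))
    if previous_stage is not None:
        prev = files.get("previous_output", previous_stage.name)
        doc.set("binCoordinates", f"{prev}.coor")
        doc.set("binVelocities", f"{prev}.vel")

    doc.set("timestep", p["timestep"])
    doc.set("cutoff", p["cutoff"])
    doc.set("switching", True)
    doc.set("switchdist", p["switch_dist"])
    doc.set("pairlistdist", p["pairlist_dist"])
    # r-RESPA: short-range every step, long-range every two steps
    doc.set("nonbondedFreq", 1)
    doc.set("fullElectFrequency", 2)
    doc.set("exclude", "scaled1-4")

    if environment.periodic:
        bx, by, bz = environment.box
        cx, cy, cz = environment.box_center
        doc.set("cellBasisVector1", f"{bx:g} 0 0")
        doc.set("cellBasisVector2", f"0 {by:g} 0")
        doc.set("cellBasisVector3", f"0 0 {bz:g}")
        doc.set("cellOrigin", f"{cx:g} {cy:g} {cz:g}")
        doc.set("wrapAll", True)
        doc.set("PME", True)
        doc.set("PMEGridSpacing", p["pme_grid_spacing"])
    elif environment.kind == "implicit":
        doc.set("GBIS", True)
        doc.set("ionConcentration", environment.salt)
        doc.set("alphaCutoff", p["cutoff"] - 2.0)
    else:  # vacuum: plain cut-off electrostatics, distance-dependent screen
        doc.set("dielectric", p["dielectric_vacuum"])

    if stage.kind == "minimization":
        doc.set("temperature", 0)
        doc.set("minimize", stage.steps)
    else:
        doc.set("langevin", True)
        doc.set("langevinDamping", p["langevin_damping"])
        doc.set("langevinTemp", stage.temperature_end)
        if environment.periodic and stage.kind in ("equilibration", "production", "smd"):
            doc.set("langevinPiston", True)
            doc.set("langevinPistonTarget", p["pressure_atm"] * 1.01325)
            doc.set("langevinPistonPeriod", 200.0)
            doc.set("langevinPistonDecay", 100.0)
            doc.set("langevinPistonTemp", stage.temperature_end)
            if environment.kind == "membrane":
                doc.set("useConstantArea", environment.constant_area)
        if stage.kind == "annealing":
            doc.set("temperature", stage.temperature_start)
            doc.set("reassignFreq", _reassign_freq(stage, p))
            doc.set("reassignIncr", p["annealing_increment"])
            doc.set("reassignTemp", stage.temperature_start)
            doc.set("reassignHold", stage.temperature_end)
        elif previous_stage is None:
            doc.set("temperature", stage.temperature_start)
        doc.set("run", stage.steps)

    if stage.restrained:
        if "restraints" not in files:
            raise ProtocolError(
                f"stage {stage.name} is restrained but no restraint "
                "reference file was given"
            )
        doc.set("constraints", True)
        doc.set("consref", files["restraints"])
        doc.set("conskfile", files["restraints"])
        doc.set("conskcol", "B")
        doc.set("constraintExp", 2)

    if stage.smd is not None:
        smd = stage.smd
        doc.set("SMD", True)
        doc.set("SMDFile", files.get("smdfile", "smd_reference.pdb"))
        doc.set("SMDk", smd.spring_k)
        doc.set("SMDVel", smd.velocity)
        dx, dy, dz = smd.direction
        doc.set("SMDDir", f"{dx:.6f} {dy:.6f} {dz:.6f}")
        doc.set("SMDOutputFreq", 100)

    for key, path in doc.files.items():
        if key in ("output", "previous_output"):
            continue
        if not path:
            logger.warning("config %s references empty %s path", stage.name, key)
    return doc


def _reassign_freq(stage: ProtocolStage, p: dict) -> int:
    n_incr = max(
        1,
        int(np.ceil(
            (stage.temperature_end - stage.temperature_start)
            / p["annealing_increment"]
        )),
    )
    return max(1, stage.steps // n_incr)


# ---------------------------------------------------------------------------
# Selections and restraint references
# ---------------------------------------------------------------------------

def select_atoms(system: MolecularSystem, selection) -> list[int]:
    """Resolve a selection to atom indices.

    Accepts a callable predicate over :class:`Atom`, a list of indices, or
    one of the named selections ``backbone``, ``protein`` (any non-water,
    non-ion segment), ``all``, ``none``, ``segid:<ID>``,
    ``resid:<SEG>:<N>[-<M>]``.
    """
    if callable(selection):
        return [i for i, a in enumerate(system.atoms) if selection(a)]
    if isinstance(selection, (list, tuple, set)):
        return sorted(int(i) for i in selection)
    sel = str(selection).strip()
    water_ion = {"TP3W", "TIP3", "HOH", "WAT", "SOD", "CLA", "POT", "MG", "CAL"}
    if sel == "backbone":
        return [
            i for i, a in enumerate(system.atoms)
            if a.name in BACKBONE_NAMES and a.resname not in water_ion
        ]
    if sel == "protein":
        return [i for i, a in enumerate(system.atoms) if a.resname not in water_ion]
    if sel == "all":
        return list(range(len(system.atoms)))
    if sel == "none":
        return []
    if sel.startswith("segid:"):
        segid = sel.split(":", 1)[1]
        return [i for i, a in enumerate(system.atoms) if a.segid == segid]
    if sel.startswith("resid:"):
        _, segid, rng = sel.split(":")
        lo, _, hi = rng.partition("-")
        lo_i, hi_i = int(lo), int(hi or lo)
        return [
            i for i, a in enumerate(system.atoms)
            if a.segid == segid and lo_i <= a.resid <= hi_i
        ]
    raise ProtocolError(f"unrecognized selection {selection!r}")


def write_restraint_reference(
    system: MolecularSystem,
    selection,
    k: float,
) -> str:
    """PDB text whose B-factor column holds ``k`` on the selected atoms.

    Unselected atoms carry 0.0 and so feel no restraint.  An empty
    selection is allowed (the file is still valid, all-zero) but warned
    about, since it usually signals a selection typo.
    """
    idx = select_atoms(system, selection)
    if not idx:
        logger.warning("restraint selection matched no atoms; writing all-zero column")
    bf = np.zeros(len(system.atoms))
    bf[list(idx)] = float(k)
    return write_pdb(system, bfactors=bf)


def setup_smd(
    system: MolecularSystem,
    anchor_selection,
    pull_selection,
    velocity: float,
    spring_k: float | None = None,
) -> tuple[SMDSpec, str]:
    """Prepare constant-velocity pulling inputs.

    The pulling direction is the unit vector from the anchor-group centroid
    to the pull-group centroid.  Returns the :class:`SMDSpec` and the SMD
    reference PDB text, in which anchor atoms are marked fixed (occupancy
    column 1) and pull atoms tagged as the SMD group (B-factor column 1).
    Anchor and pull selections must be non-empty and disjoint.
    """
    anchors = select_atoms(system, anchor_selection)
    pulls = select_atoms(system, pull_selection)
    if not anchors or not pulls:
        raise ProtocolError("anchor and pull selections must be non-empty")
    if set(anchors) & set(pulls):
        raise ProtocolError("anchor and pull selections overlap")
    coords = system.coordinates()
    a_centroid = coords[anchors].mean(axis=0)
    p_centroid = coords[pulls].mean(axis=0)
    vec = p_centroid - a_centroid
    norm = float(np.linalg.norm(vec))
    if norm < 1e-9:
        raise ProtocolError("anchor and pull centroids coincide; direction undefined")
    direction = tuple(float(v) for v in vec / norm)
    spec = SMDSpec(
        velocity=float(velocity),
        spring_k=float(spring_k if spring_k is not None else DEFAULTS["smd_spring_k"]),
        anchor_selection=str(anchor_selection),
        pull_selection=str(pull_selection),
        direction=direction,
    )
    # reference file: occupancy marks fixed anchors, B-factor tags SMD atoms
    bf = np.zeros(len(system.atoms))
    bf[pulls] = 1.0
    text = write_pdb(system, bfactors=bf)
    lines = text.splitlines()
    atom_i = 0
    for li, line in enumerate(lines):
        if not line.startswith("ATOM"):
            continue
        occ = 1.0 if atom_i in set(anchors) else 0.0
        lines[li] = line[:54] + f"{occ:6.2f}" + line[60:]
        atom_i += 1
    return spec, "\n".join(lines) + "\n"
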