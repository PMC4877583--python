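"""End-to-end preparation pipeline and session replay.

:func:`prepare` chains the whole workflow — structure check, segment
building, coordinate assignment, mutations and protonation edits,
internal-coordinate completion, solvation, ionization and protocol
generation — writing a *setup* folder (preparation artifacts: check
report, built-but-unsolvated structure) and a *run* folder (final
structure, coordinates and one config file per stage), plus the session
log pair in the working directory root.

Everything is deterministic for a fixed seed, so running :func:`prepare`
twice with identical inputs yields byte-identical setup and run folders;
:func:`replay_session` exploits that to regenerate a recorded preparation
and verify every output digest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import builder, coordinates, protocol, solvation, structure_check
from .session import (
    SessionError,
    SessionRecord,
    load_session,
    record_action,
    sha256_text,
    write_session,
)
from .solvation import DEFAULT_EXCLUSION_RADIUS, DEFAULT_PADDING, DEFAULT_SALT_CONCENTRATION
from .system_model import MolecularSystem, read_pdb, write_pdb, write_psf
from .topology import TopologySet, merge_topologies, parse_topology

__all__ = ["PrepareOptions", "PrepareResult", "prepare", "replay_session"]


@dataclass
class PrepareOptions:
    """Everything :func:`prepare` needs beyond the structure and topology.

    ``mutations`` entries are (segid, resid, new_resname); ``protonations``
    are (segid, resid, variant).  ``environment`` selects the Table-style
    parameter block; solvation/ionization only run for periodic
    environments.  The ``seed`` drives the single stochastic step
    (ion placement).
    """

    environment: str = "explicit"
    salt: float = DEFAULT_SALT_CONCENTRATION
    padding: float = DEFAULT_PADDING
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS
    target_temperature: float = 300.0
    seed: int = 1
    chains: list[str] | None = None
    mutations: list[tuple[str, int, str]] = field(default_factory=list)
    protonations: list[tuple[str, int, str]] = field(default_factory=list)
    first_patch: str | None = None
    last_patch: str | None = None
    protocol_overrides: dict = field(default_factory=dict)

    def to_params(self) -> dict:
        return {
            "environment": self.environment,
            "salt": self.salt,
            "padding": self.padding,
            "exclusion_radius": self.exclusion_radius,
            "target_temperature": self.target_temperature,
            "chains": self.chains,
            "mutations": [list(m) for m in self.mutations],
            "protonations": [list(p) for p in self.protonations],
            "first_patch": self.first_patch,
            "last_patch": self.last_patch,
            "protocol_overrides": dict(self.protocol_overrides),
        }

    @classmethod
    def from_params(cls, params: dict, seed: int) -> "PrepareOptions":
        return cls(
            environment=params["environment"],
            salt=params["salt"],
            padding=params["padding"],
            exclusion_radius=params["exclusion_radius"],
            target_temperature=params["target_temperature"],
            seed=seed,
            chains=params.get("chains"),
            mutations=[tuple(m) for m in params.get("mutations", [])],
            protonations=[tuple(p) for p in params.get("protonations", [])],
            first_patch=params.get("first_patch"),
            last_patch=params.get("last_patch"),
            protocol_overrides=dict(params.get("protocol_overrides", {})),
        )


@dataclass
class PrepareResult:
    system: MolecularSystem
    report: structure_check.StructureReport
    guess: coordinates.GuessReport
    ion_report: solvation.IonReport | None
    n_waters: int
    stages: list[protocol.ProtocolStage]
    session: SessionRecord
    workdir: Path

    @property
    def run_dir(self) -> Path:
        return self.workdir / "run"

    @property
    def setup_dir(self) -> Path:
        return self.workdir / "setup"


def _write(path: Path, text: str, digests: dict) -> None:
    path.write_text(text)
    digests[path.name] = sha256_text(text)


def prepare(
    pdb_text: str,
    topology_texts: list[str],
    workdir,
    options: PrepareOptions | None = None,
    session: SessionRecord | None = None,
) -> PrepareResult:
    """Run the full preparation workflow; returns the result bundle.

    ``topology_texts`` are CHARMM-dialect topology documents, merged
    last-wins.  ``workdir`` receives ``setup/``, ``run/`` and the session
    log pair.
    """
    options = options or PrepareOptions()
    workdir = Path(workdir)
    setup_dir = workdir / "setup"
    run_dir = workdir / "run"
    setup_dir.mkdir(parents=True, exist_ok=True)
    run_dir.mkdir(parents=True, exist_ok=True)
    session = session if session is not None else SessionRecord()
    input_digests = {
        "structure.pdb": sha256_text(pdb_text),
        **{f"topology_{i}": sha256_text(t) for i, t in enumerate(topology_texts)},
    }

    sets = [parse_topology(t) for t in topology_texts]
    topo, n_overrides = merge_topologies(sets)
    # standard water aliasing so crystallographic names resolve
    topo.aliases.add_residue_alias("HOH", "TP3W")
    topo.aliases.add_residue_alias("TIP3", "TP3W")
    record_action(
        session, "load_topology",
        {"n_files": len(topology_texts), "n_overrides": n_overrides},
        input_digests=input_digests,
    )

    structure = read_pdb(pdb_text)
    record_action(
        session, "read_structure",
        {"model": structure.model_used, "n_records": len(structure.records)},
    )
    if options.chains:
        structure = structure_check.select_chains(structure, options.chains)
        record_action(session, "select_chains", {"keep": list(options.chains)})

    report = structure_check.check_structure(structure, topo)
    out_digests: dict = {}
    _write(setup_dir / "structure_report.txt", report.to_text(), out_digests)
    record_action(
        session, "check_structure",
        {"n_issues": len(report.issues), "chains": report.selected_chains},
        output_digests={"structure_report.txt": out_digests["structure_report.txt"]},
    )

    # one segment per chain, residues in file order
    system = MolecularSystem()
    for chain in structure.chains():
        residues: list[tuple[int, str]] = []
        for rec in structure.records:
            if rec.chain != chain:
                continue
            resname = topo.aliases.resolve_residue_name(rec.resname)
            if not residues or residues[-1][0] != rec.resid:
                residues.append((rec.resid, resname))
        builder.build_segment(
            system, chain, residues, topo,
            first_patch=options.first_patch, last_patch=options.last_patch,
        )
        record_action(
            session, "build_segment",
            {"segid": chain, "n_residues": len(residues),
             "first_patch": options.first_patch, "last_patch": options.last_patch},
        )

    stats = coordinates.assign_coordinates(system, structure, topo.aliases)
    record_action(
        session, "assign_coordinates",
        {"matched": stats.matched, "unmatched": len(stats.unmatched_records),
         "still_unknown": stats.still_unknown},
    )

    for segid, resid, new_resname in options.mutations:
        delta = builder.mutate_residue(system, segid, resid, new_resname, topo)
        record_action(
            session, "mutate_residue",
            {"segid": segid, "resid": resid, "new_resname": new_resname,
             "charge_delta": round(delta["charge_delta"], 6)},
        )
    for segid, resid, variant in options.protonations:
        delta = builder.set_protonation(system, segid, resid, variant, topo)
        record_action(
            session, "set_protonation",
            {"segid": segid, "resid": resid, "variant": variant,
             "charge_delta": round(delta.get("charge_delta", 0.0), 6)},
        )

    guess = coordinates.run_ic_guessing(system, topo)
    hreport = coordinates.guess_hydrogens(system, topo)
    guess.placed.extend(hreport.placed)
    guess.heuristic.extend(hreport.heuristic)
    guess.remaining_unknown = hreport.remaining_unknown
    record_action(
        session, "guess_coordinates",
        {"placed": len(guess.placed), "heuristic": len(guess.heuristic),
         "rejected_by_angle": len(guess.rejected_by_angle),
         "remaining_unknown": len(guess.remaining_unknown)},
    )

    _write(setup_dir / "built.pdb", write_pdb(system), out_digests)
    _write(setup_dir / "built.psf", write_psf(system), out_digests)
    record_action(
        session, "write_structure",
        {"folder": "setup", "n_atoms": system.n_atoms()},
        output_digests={k: out_digests[k] for k in ("built.pdb", "built.psf")},
    )

    ion_report = None
    n_waters = 0
    env_box = None
    if options.environment in ("explicit", "membrane"):
        from .fixtures import make_water_cell  # packaged equilibrated cell

        box = solvation.compute_box(system, padding=options.padding)
        solvated, n_waters = solvation.solvate(
            system, box, make_water_cell(),
            exclusion_radius=options.exclusion_radius,
        )
        record_action(
            session, "solvate",
            {"padding": options.padding, "box_edge": round(box.edge, 6),
             "exclusion_radius": options.exclusion_radius, "n_waters": n_waters},
        )
        system, ion_report = solvation.ionize(
            solvated, target_concentration=options.salt, rng_seed=options.seed,
        )
        record_action(
            session, "ionize",
            {"salt": options.salt,
             "n_neutralizing": ion_report.n_neutralizing,
             "species": ion_report.neutralizing_species,
             "n_salt_pairs": ion_report.n_salt_pairs,
             "final_charge": round(ion_report.final_charge, 6)},
            seed=options.seed,
        )
        env_box = (box.edge, box.edge, box.edge)
        env = protocol.EnvironmentSpec(
            kind=options.environment, box=env_box, salt=options.salt,
            box_center=tuple(round(float(v), 6) for v in box.center),
        )
    else:
        env = protocol.EnvironmentSpec(kind=options.environment, salt=options.salt)

    _write(run_dir / "system.pdb", write_pdb(system), out_digests)
    _write(run_dir / "system.psf", write_psf(system), out_digests)

    stages = protocol.default_protocol(
        env, target_temperature=options.target_temperature,
        overrides=options.protocol_overrides,
    )
    restraint_k = max((s.restraint_k for s in stages), default=0.0)
    _write(
        run_dir / "restraints.pdb",
        protocol.write_restraint_reference(system, "backbone", restraint_k),
        out_digests,
    )
    files = {
        "structure": "system.psf",
        "coordinates": "system.pdb",
        "restraints": "restraints.pdb",
    }
    prev = None
    config_names = []
    for stage in stages:
        stage_files = dict(files, output=stage.name)
        if prev is not None:
            stage_files["previous_output"] = prev.name
        doc = protocol.generate_config(
            stage, env, stage_files, previous_stage=prev,
            overrides=options.protocol_overrides,
        )
        fname = f"{stage.name}.conf"
        _write(run_dir / fname, doc.to_text(), out_digests)
        config_names.append(fname)
        prev = stage
    record_action(
        session, "generate_protocol",
        {"environment": options.environment,
         "target_temperature": options.target_temperature,
         "stages": [s.name for s in stages],
         "steps": [s.steps for s in stages],
         "restraint_k": restraint_k,
         "box": list(env_box) if env_box else None,
         "overrides": dict(options.protocol_overrides),
         "options": options.to_params()},
        seed=options.seed,
        output_digests={
            k: out_digests[k]
            for k in ["system.pdb", "system.psf", "restraints.pdb"] + config_names
        },
    )

    write_session(session, workdir)
    return PrepareResult(
        system=system, report=report, guess=guess, ion_report=ion_report,
        n_waters=n_waters, stages=stages, session=session, workdir=workdir,
    )


def replay_session(
    machine_file,
    pdb_text: str,
    topology_texts: list[str],
    workdir,
    overrides: dict | None = None,
) -> PrepareResult:
    """Re-run a recorded preparation and verify its output digests.

    Inputs must match the recorded digests (error identifies the file).
    With ``overrides`` the replay is allowed to diverge: the divergence is
    reported on the result (``digest_mismatches`` attribute) and a fresh
    session is written for the new run.
    """
    record = load_session(machine_file)
    first = record.actions[0]
    expect = first.input_digests
    if expect.get("structure.pdb") not in (None, sha256_text(pdb_text)):
        raise SessionError("input digest mismatch: structure.pdb was modified")
    for i, t in enumerate(topology_texts):
        key = f"topology_{i}"
        if expect.get(key) not in (None, sha256_text(t)):
            raise SessionError(f"input digest mismatch: topology file {i} was modified")

    proto_action = next(
        (a for a in record.actions if a.name == "generate_protocol"), None
    )
    if proto_action is None:
        raise SessionError("session records no generate_protocol action; cannot replay")
    params = proto_action.params["options"]
    seed = proto_action.seed if proto_action.seed is not None else 1
    options = PrepareOptions.from_params(params, seed)
    if overrides:
        for k, v in overrides.items():
            setattr(options, k, v)

    result = prepare(pdb_text, topology_texts, workdir, options)

    recorded: dict[str, str] = {}
    for a in record.actions:
        recorded.update(a.output_digests)
    regenerated: dict[str, str] = {}
    for a in result.session.actions:
        regenerated.update(a.output_digests)
    mismatches = sorted(
        name for name, digest in recorded.items()
        if regenerated.get(name) != digest
    )
    if mismatches and not overrides:
        raise SessionError(
            f"replay diverged from recorded digests: {mismatches}"
        )
    result.digest_mismatches = mismatches  # type: ignore[attr-defined]
    return result
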