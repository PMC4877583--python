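"""Replayable session logs.

Every preparation action is recorded with its full parameter set —
defaults included, so the record is self-describing — plus any RNG seed
and the SHA-256 digests of input and output files.  Two companion files
are written: a machine-readable YAML document that can drive an exact
replay, and a human-readable ``.infoMD``-style text meant for sharing how
a system was prepared.

The machine format is deliberately a structured data document rather than
an executable script: replay re-runs the pipeline through the library, so
loading a session can never execute arbitrary code.  A converter to a
shell-invocable command file is provided for convenience.

Replaying on inputs whose digests match the record reproduces every output
byte-for-byte (the ionization draw is seeded); an input digest mismatch is
an error naming the file.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

__all__ = [
    "SessionRecord",
    "SessionError",
    "REGISTERED_OPERATIONS",
    "record_action",
    "write_session",
    "load_session",
    "session_to_script",
    "sha256_text",
    "sha256_file",
]


class SessionError(ValueError):
    pass


#: Operations a session may record; anything else is a programming error.
REGISTERED_OPERATIONS = frozenset(
    {
        "load_topology",
        "read_structure",
        "select_chains",
        "check_structure",
        "build_segment",
        "assign_coordinates",
        "mutate_residue",
        "set_protonation",
        "apply_patch",
        "guess_coordinates",
        "solvate",
        "ionize",
        "write_structure",
        "generate_protocol",
        "setup_smd",
        "analyze",
    }
)

_PHASE_OF = {
    "load_topology": "check",
    "read_structure": "check",
    "select_chains": "check",
    "check_structure": "check",
    "build_segment": "build",
    "assign_coordinates": "build",
    "mutate_residue": "build",
    "set_protonation": "build",
    "apply_patch": "build",
    "guess_coordinates": "build",
    "write_structure": "build",
    "solvate": "solvate",
    "ionize": "solvate",
    "generate_protocol": "protocol",
    "setup_smd": "protocol",
    "analyze": "protocol",
}

PHASES = ("check", "build", "solvate", "protocol")


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def sha256_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class Action:
    name: str
    params: dict
    seed: int | None = None
    input_digests: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "params": self.params,
            "seed": self.seed,
            "input_digests": self.input_digests,
            "output_digests": self.output_digests,
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Action":
        return cls(
            name=d["name"],
            params=dict(d.get("params") or {}),
            seed=d.get("seed"),
            input_digests=dict(d.get("input_digests") or {}),
            output_digests=dict(d.get("output_digests") or {}),
            timestamp=d.get("timestamp", ""),
        )


@dataclass
class SessionRecord:
    """Append-only ordered action log."""

    actions: list[Action] = field(default_factory=list)
    created: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat(timespec="seconds")

    def __len__(self) -> int:
        return len(self.actions)

    def to_dict(self) -> dict:
        return {
            "format": "mdprep-session-1",
            "created": self.created,
            "actions": [a.to_dict() for a in self.actions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionRecord":
        if d.get("format") != "mdprep-session-1":
            raise SessionError(f"unrecognized session format {d.get('format')!r}")
        return cls(
            actions=[Action.from_dict(a) for a in d.get("actions", [])],
            created=d.get("created", ""),
        )

    def equivalent(self, other: "SessionRecord") -> bool:
        """Same actions with the same parameters and digests (timestamps ignored)."""
        if len(self.actions) != len(other.actions):
            return False
        for a, b in zip(self.actions, other.actions):
            if (a.name, a.params, a.seed, a.input_digests, a.output_digests) != (
                b.name, b.params, b.seed, b.input_digests, b.output_digests
            ):
                return False
        return True


def record_action(
    session: SessionRecord,
    name: str,
    params: dict,
    seed: int | None = None,
    input_digests: dict | None = None,
    output_digests: dict | None = None,
) -> SessionRecord:
    """Append one action; ``name`` must be a registered operation.

    Parameters are stored verbatim — callers pass the *effective* values,
    defaults in force included, so the record alone describes the run.
    """
    if name not in REGISTERED_OPERATIONS:
        raise SessionError(f"unregistered operation {name!r}")
    session.actions.append(
        Action(
            name=name,
            params=dict(params),
            seed=seed,
            input_digests=dict(input_digests or {}),
            output_digests=dict(output_digests or {}),
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )
    )
    return session


def write_session(session: SessionRecord, directory) -> tuple[Path, Path]:
    """Write the machine (YAML) and human (.infoMD) files; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    machine = directory / "session.yaml"
    human = directory / "session.infoMD"
    machine.write_text(
        yaml.safe_dump(session.to_dict(), sort_keys=False, default_flow_style=False)
    )
    human.write_text(_render_info(session))
    return machine, human


def load_session(path) -> SessionRecord:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise SessionError(f"{path}: not a session document")
    return SessionRecord.from_dict(data)


def _render_info(session: SessionRecord) -> str:
    lines = [
        "=" * 66,
        "mdprep preparation log",
        f"created: {session.created}",
        f"actions: {len(session.actions)}",
        "=" * 66,
    ]
    for phase in PHASES:
        lines.append("")
        lines.append(f"--- {phase} " + "-" * (60 - len(phase)))
        phase_actions = [
            a for a in session.actions if _PHASE_OF.get(a.name) == phase
        ]
        if not phase_actions:
            lines.append("(no actions)")
        for a in phase_actions:
            lines.append(f"* {a.name}" + (f"  [seed {a.seed}]" if a.seed is not None else ""))
            for k in sorted(a.params):
                lines.append(f"    {k} = {a.params[k]!r}")
            for fname, digest in sorted(a.output_digests.items()):
                lines.append(f"    -> {fname}  sha256:{digest[:16]}")
    lines.append("")
    return "\n".join(lines) + "\n"


def session_to_script(session: SessionRecord) -> str:
    """Render the session as an equivalent sequence of CLI invocations.

    Informational: the supported replay path is :func:`load_session` plus
    the pipeline's replay entry point, which also verifies digests.
    """
    out = ["#!/bin/sh", "# regenerated from an mdprep session log"]
    for a in session.actions:
        args = " ".join(f"--{k} {v!r}" for k, v in sorted(a.params.items()))
        seed = f" --seed {a.seed}" if a.seed is not None else ""
        out.append(f"mdprep {a.name.replace('_', '-')} {args}{seed}")
    return "\n".join(out) + "\n"
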