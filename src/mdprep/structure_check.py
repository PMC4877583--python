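"""Automated consistency checks on input structures and chain selection.

Experimental structures routinely arrive with missing residues, missing
side-chain atoms, alternate conformations, multiple NMR models or residue
names the force field does not know.  :func:`check_structure` surfaces all
detectable proxies of these problems as an ordered issue list; the caller
(or the user reading the report) decides what to do about each.  Gaps at
chain termini are deliberately not flagged — a truncated terminus is a
normal modelling choice, only interior discontinuities need attention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system_model import PdbRecord, PdbStructure
from .topology import TopologySet, UnknownResidueError, resolve_residue

__all__ = [
    "ISSUE_KINDS",
    "StructureIssue",
    "StructureReport",
    "check_structure",
    "select_chains",
    "CHAIN_BREAK_DISTANCE",
]

#: Peptide-bond C-N distance (Angstrom) above which consecutive residues
#: are reported as a chain break (ideal is ~1.33).
CHAIN_BREAK_DISTANCE = 2.0

ISSUE_KINDS = (
    "sequence_gap",
    "unknown_residue",
    "missing_atoms",
    "altloc",
    "multi_model",
    "nonpositive_occupancy",
    "chain_break_distance",
)


@dataclass(frozen=True)
class StructureIssue:
    kind: str
    chain: str
    resid_range: tuple[int, int]
    detail: str

    def __str__(self) -> str:
        lo, hi = self.resid_range
        where = f"{self.chain}:{lo}" if lo == hi else f"{self.chain}:{lo}-{hi}"
        return f"[{self.kind}] {where}: {self.detail}"


@dataclass
class StructureReport:
    issues: list[StructureIssue] = field(default_factory=list)
    selected_chains: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def by_kind(self, kind: str) -> list[StructureIssue]:
        return [i for i in self.issues if i.kind == kind]

    def to_text(self) -> str:
        lines = [f"structure check: {len(self.issues)} issue(s)"]
        lines += [str(i) for i in self.issues]
        lines.append("chains: " + ", ".join(self.selected_chains))
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "n_issues": len(self.issues),
            "chains": list(self.selected_chains),
            "issues": [
                {
                    "kind": i.kind,
                    "chain": i.chain,
                    "resid_range": list(i.resid_range),
                    "detail": i.detail,
                }
                for i in self.issues
            ],
        }


def _residues_in_order(records: list[PdbRecord]) -> dict[str, list[tuple[int, str, list[PdbRecord]]]]:
    chains: dict[str, list[tuple[int, str, list[PdbRecord]]]] = {}
    for rec in records:
        chain = chains.setdefault(rec.chain, [])
        key = (rec.resid, rec.insertion)
        if not chain or (chain[-1][0], chain[-1][1]) != key:
            chain.append((rec.resid, rec.insertion, [rec]))
        else:
            chain[-1][2].append(rec)
    return chains


def check_structure(structure: PdbStructure, topo: TopologySet) -> StructureReport:
    """Run every structural consistency check; pure, never mutates input.

    Flags: interior residue-number discontinuities (``sequence_gap``),
    residue names unresolvable against the topology (``unknown_residue``),
    residues missing template heavy atoms (``missing_atoms``), alternate
    locations collapsed by the reader (``altloc``), multi-model input
    (``multi_model``), records with occupancy <= 0
    (``nonpositive_occupancy``) and consecutive-residue C-N distances above
    :data:`CHAIN_BREAK_DISTANCE` (``chain_break_distance``).
    """
    report = StructureReport(selected_chains=structure.chains())

    if structure.n_models > 1:
        report.issues.append(
            StructureIssue(
                "multi_model", "*", (0, 0),
                f"{structure.n_models} models present; model "
                f"{structure.model_used} used",
            )
        )
    for chain, resid, name in structure.altloc_dropped:
        report.issues.append(
            StructureIssue(
                "altloc", chain, (resid, resid),
                f"alternate location of atom {name} dropped "
                "(first altloc kept)",
            )
        )

    chains = _residues_in_order(structure.records)
    for chain_id, residues in chains.items():
        for (r1, i1, recs1), (r2, i2, recs2) in zip(residues, residues[1:]):
            if i1 == i2 == "" and r2 - r1 > 1:
                report.issues.append(
                    StructureIssue(
                        "sequence_gap", chain_id, (r1, r2),
                        f"residue numbering jumps from {r1} to {r2}",
                    )
                )
            # peptide-bond geometry between consecutive numbered residues
            if r2 - r1 == 1:
                c = next((r for r in recs1 if r.name == "C"), None)
                n = next((r for r in recs2 if r.name == "N"), None)
                if c is not None and n is not None:
                    d = float(np.linalg.norm(c.xyz - n.xyz))
                    if d > CHAIN_BREAK_DISTANCE:
                        report.issues.append(
                            StructureIssue(
                                "chain_break_distance", chain_id, (r1, r2),
                                f"C-N distance {d:.2f} A exceeds "
                                f"{CHAIN_BREAK_DISTANCE} A",
                            )
                        )
        for resid, insertion, recs in residues:
            resname = recs[0].resname
            try:
                template = resolve_residue(resname, topo)
            except UnknownResidueError:
                report.issues.append(
                    StructureIssue(
                        "unknown_residue", chain_id, (resid, resid),
                        f"residue type {resname!r} not in topology",
                    )
                )
                continue
            present = {r.name for r in recs}
            heavy = {
                a.name for a in template.atoms
                if not (a.mass and a.mass < 3.5) and not a.name.startswith("H")
            }
            missing = heavy - present
            if missing:
                report.issues.append(
                    StructureIssue(
                        "missing_atoms", chain_id, (resid, resid),
                        f"{resname} missing heavy atoms: "
                        + ", ".join(sorted(missing)),
                    )
                )
        for resid, insertion, recs in residues:
            for r in recs:
                if r.occupancy <= 0.0:
                    report.issues.append(
                        StructureIssue(
                            "nonpositive_occupancy", chain_id, (resid, resid),
                            f"atom {r.name} has occupancy {r.occupancy:g}",
                        )
                    )
    return report


def select_chains(structure: PdbStructure, keep) -> PdbStructure:
    """Filter a decoded structure down to the requested chains.

    Raises ``ValueError`` listing the available chains when a requested
    chain does not exist.  Keeping every chain returns an equal structure.
    """
    keep = list(keep)
    if not keep:
        raise ValueError("select_chains: empty selection")
    available = structure.chains()
    missing = [c for c in keep if c not in available]
    if missing:
        raise ValueError(
            f"chain(s) {missing} not present; available: {available}"
        )
    records = [r for r in structure.records if r.chain in keep]
    return PdbStructure(
        records=records,
        n_models=structure.n_models,
        model_used=structure.model_used,
        altloc_dropped=[t for t in structure.altloc_dropped if t[0] in keep],
    )
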