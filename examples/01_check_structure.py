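"""Structure checking: find the problems a raw PDB brings along.

Builds a toy peptide PDB with an interior numbering gap and a missing
carbonyl oxygen on every residue, then runs the automated checks.
"""

from mdprep.fixtures import make_toy_peptide_pdb, mini_topology_set
from mdprep.structure_check import check_structure
from mdprep.system_model import read_pdb

topo = mini_topology_set()
pdb = make_toy_peptide_pdb(4, gap_after=2, missing={"O"})
report = check_structure(read_pdb(pdb), topo)

print(report.to_text())
# Each line is one issue: a sequence_gap where residue numbering jumps
# (interior gaps only - truncated termini are a normal modelling choice)
# and a missing_atoms entry per residue lacking a template heavy atom.
print(f"summary: {len(report.by_kind('sequence_gap'))} gap(s), "
      f"{len(report.by_kind('missing_atoms'))} residue(s) with missing atoms")
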