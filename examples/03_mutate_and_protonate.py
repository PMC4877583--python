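"""Point mutation and protonation-state editing.

Mutates the middle glycine of a peptide to the cysteine-like residue
(backbone coordinates survive; the new side chain is rebuilt from internal
coordinates), then protonates an aspartate-like residue via a patch.
"""

from mdprep.builder import mutate_residue, set_protonation
from mdprep.coordinates import run_ic_guessing
from mdprep.fixtures import build_toy_peptide, mini_topology_set

topo = mini_topology_set()
system = build_toy_peptide(3, resnames=["GLY", "GLY", "ASP"], topo=topo)
print(f"start: {system.n_atoms()} atoms, net charge {system.total_charge():+.2f} e")

delta = mutate_residue(system, "P", 2, "CYS", topo)
print(f"GLY2->CYS: kept {delta['kept']} (coordinates preserved), "
      f"added {delta['added']} (to be placed)")

delta = set_protonation(system, "P", 3, "ASPP", topo)
print(f"ASP3 protonated: +{len(delta['added'])} atom, "
      f"charge delta {delta['charge_delta']:+.2f} e")

report = run_ic_guessing(system, topo)
print(f"rebuilt side chains placed by IC guessing; "
      f"{report.n_remaining} atoms unknown")
print(f"final: {system.n_atoms()} atoms, net charge {system.total_charge():+.2f} e")
# the charge moved from -1 (deprotonated acid) to 0 - exactly the proton
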