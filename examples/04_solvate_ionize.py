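"""Solvation and ionization: cubic box, tiled water, physiological NaCl.

The box edge is the solute extent plus twice the padding; waters come from
tiling a 64-molecule unit cell and pruning clashes; ions replace randomly
chosen waters (seeded, hence reproducible).
"""

from mdprep.fixtures import build_toy_peptide, make_water_cell, mini_topology_set
from mdprep.solvation import compute_box, ionize, solvate

topo = mini_topology_set()
peptide = build_toy_peptide(3, resnames=["GLY", "ASP", "ASP"], topo=topo)
print(f"solute: {peptide.n_atoms()} atoms, charge {peptide.total_charge():+.0f} e")

box = compute_box(peptide, padding=8.0)
print(f"cubic box edge {box.edge:.1f} A centered on the solute")

solvated, n_waters = solvate(peptide, box, make_water_cell(), exclusion_radius=2.4)
print(f"placed {n_waters} waters (none within 2.4 A of a solute heavy atom)")

system, report = ionize(solvated, target_concentration=0.15, rng_seed=7)
print(f"neutralized with {report.n_neutralizing} {report.neutralizing_species}, "
      f"added {report.n_salt_pairs} NaCl pairs "
      f"(round(0.15 x {n_waters} / 55.5))")
print(f"final net charge: {report.final_charge:+.6f} e "
      "- exactly zero, as an Ewald-summed simulation requires")
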