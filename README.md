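# mdprep

Scriptable preparation of all-atom molecular-dynamics systems, for people
who want the convenience of an automated setup tool with the auditability
of a library: every step is a plain Python call, every run leaves a
replayable log.

Starting from a PDB structure and CHARMM-format residue topology files
(`.rtf`/`.str`), mdprep

- **checks** the input for the usual experimental-structure problems
  (sequence gaps, unknown residue names, missing heavy atoms, altlocs,
  multiple models, broken chains);
- **generates the molecular topology**: segments of numbered residues are
  instantiated from residue templates, angles and dihedrals are
  autogenerated from the bond graph, terminal and linkage patches applied,
  and the result written as an X-PLOR/EXT PSF that NAMD can read;
- **completes missing atoms**: coordinates are copied from the PDB where
  present; everything else (most hydrogens, missing side-chain atoms) is
  reconstructed from the force field's internal-coordinate (IC) records by
  fixpoint iteration, with tetrahedral/trigonal heuristics for hydrogens
  that have no IC record. Placements that would create a bond angle below
  45° are rejected. Written PDBs encode coordinate provenance in the
  occupancy column: `1` read from a file, `0` guessed, `-1` unknown;
- **edits**: point mutations (backbone atoms keep their coordinates, the
  new side chain is rebuilt from ICs) and protonation-state changes
  (histidine tautomers by template rename, acids by patch);
- **solvates and ionizes**: a cubic box (solute extent + 2×padding), water
  by unit-cell tiling, neutralizing counterions plus NaCl at a target
  concentration — `N_pairs = round(c · N_waters / 55.5)` — by seeded random
  water replacement, so the final net charge is exactly 0;
- **writes simulation protocols**: one NAMD-style config file per stage of
  a minimization → temperature-annealing → equilibration → production
  ladder (annealing + equilibration span 1 ns at the 2 fs timestep), with
  environment-appropriate settings — periodic cell + PME for explicit
  solvent and membranes, GBIS for implicit solvent, dielectric 80 for
  vacuum — a 12.0 Å nonbonded cutoff, and r-RESPA long-range evaluation
  every 2 steps. Backbone restraints use a reference PDB whose B-factor
  column carries the force constant; constant-velocity steered MD (anchor
  group, pull group, harmonic spring) is supported;
- **analyzes**: Kabsch-superposition RMSD series, per-residue RMSF,
  geometric hydrogen-bond counts, and NAMD energy-log parsing;
- **documents**: a machine-readable session log (YAML) that replays the
  whole preparation byte-for-byte, and a human-readable `.infoMD`-style
  companion.

The package ships a synthetic mini force field and toy-structure
generators (`mdprep.fixtures`) so every test and example is self-contained;
real CHARMM36 files use the same code paths.

## Worked example

```python
from mdprep.fixtures import make_mini_topology, make_toy_peptide_pdb
from mdprep.pipeline import PrepareOptions, prepare

pdb = make_toy_peptide_pdb(3, resnames=["GLY", "CYS", "ASP"])
options = PrepareOptions(
    environment="explicit", salt=0.15, padding=6.0, seed=42,
    mutations=[("P", 1, "ALA")],       # point-mutate residue 1
    protonations=[("P", 3, "ASPP")],   # protonate the acid side chain
)
result = prepare(pdb, [make_mini_topology()], "prep", options)
print(result.n_waters, result.ion_report.n_salt_pairs,
      round(result.system.total_charge(), 6))
```

prints

```
951 3 -0.0
```

meaning: 951 waters were placed in the box, `round(0.15 × 951 / 55.5) = 3`
NaCl pairs were added on top of the neutralizing ions, and the final net
charge is exactly zero. The working directory now holds `setup/` (check
report, built structure), `run/` (final `system.psf`/`system.pdb`,
restraint reference, `min.conf`, `annealing.conf`, `equilibration.conf`,
`production.conf`) and the `session.yaml`/`session.infoMD` log pair.
Running `prepare` again with the same seed reproduces every file
byte-for-byte, and

```python
from mdprep.pipeline import replay_session
replay_session("prep/session.yaml", pdb, [make_mini_topology()], "prep2")
```

regenerates the folders from the log and verifies every output digest.

The `examples/` directory has one short narrative script per capability;
a thin CLI (`mdprep check|prepare|replay|analyze`) wraps the same calls
for shell use.

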