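# Methods

This note documents the models, conventions and design choices behind
mdprep: what each stage computes, the tunable parameters and their
defaults, what the synthetic test inputs do and do not emulate, and the
numerical decisions that make runs reproducible.

## Topology model

A CHARMM-format residue topology file is parsed into residue templates
(atoms with name/type/charge, bonds, impropers, CMAP cross-terms, IC
records), patch templates (`PRES`: deletions, additions/modifications,
extra bonds/impropers/ICs), a type→mass table and default terminal-patch
declarations. The supported record set is the one structure generation
consumes: `MASS`, `RESI`, `PRES`, `ATOM`, `BOND`/`DOUBLE`, `IMPR`, `CMAP`,
`IC`, `DELETE`, `PATCH`/`PATC`, `DEFA`, `AUTO`; `GROUP` and
`DONOR`/`ACCEPTOR` are recognized and ignored because nothing downstream
needs them. Parameter files (bonded/nonbonded constants) are deliberately
out of scope — mdprep prepares structures and configs, it never evaluates
energies.

Conventions worth stating:

- The residue charge declared on the `RESI` line is authoritative; a
  mismatch with the atom-charge sum beyond 1e-6 e is warned about, not
  fatal, because real force-field streams occasionally disagree in the
  last digit.
- Angles are stored in degrees and lengths in Å exactly as printed;
  radians appear only inside geometry routines. This keeps file
  round-trips exact and testable.
- `-`/`+` atom-name prefixes refer to the previous/next residue of a
  segment; in two-target patches a leading `1`/`2` selects the residue
  slot. Following CHARMM convention, a value of 0.0 in an IC length or
  angle field means "unset"; a torsion of 0.0 is a real value.
- When several topology files are merged, later definitions of the same
  residue/patch/mass win and the override count is reported. Name aliases
  (PDB residue → force-field residue, (residue, atom) → atom) resolve in a
  single step, so lookups are idempotent.

## Structure generation

Building a segment instantiates each residue template in order (atoms
appended template-order with *unknown* coordinates), realizes intra- and
inter-residue bonds, applies terminal patches (explicit argument >
per-residue `PATC` > file-wide `DEFA`; `"NONE"` suppresses), and
autogenerates angles and dihedrals from the bond graph:

- angles: exactly `{(i, j, k) : i < k, i–j and j–k bonded}`;
- dihedrals: all simple bonded 4-paths `i–j–k–l`, deduplicated under
  reversal, with no repeated atom inside a path — so a 3-ring contributes
  no proper dihedral. Both outputs are emitted in deterministic sorted
  order, and both are property-tested against an independent brute-force
  enumeration over random graphs.

Patches delete atoms first (removing every bonded term that touches them),
then add or modify atoms (an existing name is modified in place and keeps
its coordinates; a new name arrives unknown), then attach patch bonds,
impropers and IC records. Patch ICs are appended to the system's IC pool
so newly added atoms are placeable — the mutation and protonation
workflows depend on this. Angle/dihedral regeneration after a patch is
global rather than local: at the system sizes where patching happens
(before solvation) regeneration costs microseconds, and a single code path
removes a class of local-bookkeeping bugs.

Point mutation keeps every atom whose name exists in both the old and new
template (in practice the backbone), deletes the rest, adds the new
template's remaining atoms as unknown, and rebuilds the residue's bonds,
impropers and IC entries from the new template. A mutation to the same
residue is a no-op. Mutating a terminal residue that carries a terminal
patch rebuilds from the plain template (the patch must be re-applied), a
limitation shared with template-based builders generally.

Protonation states are table-driven: histidine-like tautomers and the
charged form are template renames (sharing the mutation machinery, so
common atoms keep coordinates); acid protonations are patch applications.
Re-applying the current state is a no-op for renames and an explicit error
for patches — never a silent double-add.

## Coordinate completion

`place_from_ic(a, b, c, r, θ, φ)` is the standard internal-to-Cartesian
(NeRF) construction: the returned point d satisfies |c−d| = r,
∠(b,c,d) = θ and torsion(a,b,c,d) = φ each to 1e-6. Torsions follow the
IUPAC sign convention (clockwise positive looking b→c); the convention is
fixed by a property test that recomputes (r, θ, φ) from the output. A
frame whose three atoms are collinear (sin of the angle at b below 1e-6)
raises a degenerate-frame error, since the torsion is undefined; θ = 180°
requests are honored (the point lands on the extended b→c line).

IC guessing iterates over the IC pool to a fixpoint: an entry fires
forward (place d from a, b, c) or in reverse (place a from the other
three) as soon as its three frame atoms have coordinates. For improper
records (starred third atom; a and d both bonded to c) the forward
construction is identical, and the reverse uses the identity
torsion(d,b,c,a) = −torsion(a,b,c,d). Placements are rejected when any
bond angle they would create with already-placed atoms — at the new atom
or at any bonded neighbor — falls below 45°, a named constant
(`MIN_BOND_ANGLE_DEG`). The sweep count is bounded by the atom count so
cyclic IC dependencies terminate. Successful placements are marked
*guessed*; atoms that remain unknown are reported, never fatal, and write
occupancy −1.

Hydrogens with no IC record are placed heuristically from their bonded
parent's pattern: a parent with 4 graph neighbors gets tetrahedral
completion, 3 neighbors trigonal-planar; open slots are filled against the
unit vectors to already-placed neighbors (opposite-of-sum for the last
slot, the half-angle construction for two missing tetrahedral slots, a
deterministic perpendicular for under-determined cases). X–H bond lengths
default to C–H 1.09 Å, N–H 1.01 Å, O–H 0.96 Å, S–H 1.34 Å, configurable.
These values are conventional equilibrium lengths; the placement is
geometric, not energetic, and minimization is expected to relax it.

Because two different IC records may place the same atom (e.g. a carbonyl
oxygen via an improper against the next residue and via a backbone
fallback), the packaged fixture force field keeps such duplicate routes
geometrically consistent; the order-independence of guessing is tested by
permuting the IC pool.

## Structure checks

Seven detectable problem classes are flagged: interior residue-number
discontinuities (termini are exempt — a truncated end is a modelling
choice, not an error), residue names unresolvable against the topology,
residues missing template heavy atoms, alternate locations (the reader
keeps the alphabetically first altloc and reports the collapse), multiple
models (model 1 is used by default and the choice is surfaced),
non-positive occupancies, and consecutive-residue C–N distances above
2.0 Å (ideal peptide ≈ 1.33 Å; 2.0 Å separates bonded from broken at any
realistic resolution). The checker is pure — it never mutates its input —
and each kind has a dedicated triggering fixture in the test matrix.
Chirality/stereochemistry validation and missing-loop building are out of
scope.

## Solvation and ionization

The box is cubic: edge = max per-axis solute extent + 2 × padding
(default 10 Å), centered on the solute extent midpoint. Water comes from
tiling a pre-built unit cell over the box and deleting molecules with any
atom outside the box or any atom within the exclusion radius (default
2.4 Å) of a solute heavy atom; clash search uses a k-d tree. Waters are
appended as fresh `WTn` segments capped at 9999 residues so PDB resid
fields stay in range.

Ionization first zeroes the integer net charge (Na⁺ for negative solutes,
Cl⁻ for positive; a non-integral charge beyond 1e-3 e is an error, since
it indicates a broken topology), then adds
`N = round(c · N_waters / 55.5)` salt pairs — concentration referenced to
the 55.5 mol/L molarity of pure water, the convention of common
autoionization tools; the constant is configurable. Each ion replaces one
whole randomly chosen water and takes its oxygen position. The draw uses a
dedicated seeded generator, making ionization (and hence the whole
pipeline) bit-reproducible; no minimum ion–solute distance is imposed.
The physiological default is 0.15 mol/L NaCl.

## Protocols

The default ladder is minimization (1000 steps) → annealing →
equilibration → production, with annealing + equilibration spanning 1 ns
at the 2 fs timestep (500,000 steps, split 1:3 — the split is a free
choice; only the 1 ns total is contractual) and production defaulting to
another 500,000 steps. Annealing ramps from 60 K to the target (default
300 K) in 25 K reassignment increments with the backbone restrained;
equilibration holds the target, still restrained; production runs free.

Environment determines electrostatics and boundaries: explicit solvent
and membrane get a periodic cell, PME (grid spacing 1.0 Å) and, for
dynamics stages past annealing, a Langevin barostat at 1 atm (membranes
optionally constant-area); implicit solvent gets GBIS with the salt
concentration; vacuum gets plain cutoff electrostatics with dielectric 80.
Common to all: 12.0 Å cutoff with switching from 10.0 Å, 13.5 Å pairlist,
r-RESPA with long-range forces every 2 steps, Langevin damping 1 ps⁻¹.
Every default is overridable per call and recorded in the session log, so
a run is self-describing.

Restraints use a reference PDB whose B-factor column holds the force
constant (default 2.0 kcal mol⁻¹ Å⁻² on the backbone) — selected atoms
carry k, everything else 0. SMD setup takes disjoint non-empty anchor and
pull selections; the pulling direction is the unit vector between their
centroids, the reference file marks anchors fixed (occupancy column) and
pull atoms tagged (B-factor column), and velocity (user-mandatory, no
default) and spring constant (default 7.0 kcal mol⁻¹ Å⁻²) pass verbatim
into the config. Configs are ordered `key value` text and parse back into
equal documents.

## Analysis

Superposition is the Kabsch SVD solution with the reflection branch
folded back (smallest singular direction negated when det < 0), so the
rotation is always proper — property-tested on random and deliberately
planar point sets. RMSD series are frame-0-referenced, optionally after
superposition on the selection. RMSF iteratively superposes frames onto
the running mean structure (≤5 rounds, usually converged in 2) before
measuring per-atom fluctuation, then averages over each residue's
selected atoms. Hydrogen bonds use the geometric criterion
donor–acceptor ≤ 3.5 Å and donor–H–acceptor ≥ 150°, both exposed as
parameters. Energy logs are parsed by mapping `ENERGY:` rows through the
most recent `ETITLE:` header, so restarts that reprint a permuted header
remap cleanly. Trajectories are multi-MODEL PDB text; binary formats are
out of scope here (analysis operates on arrays, so any reader can feed
it).

## Sessions and replay

Every pipeline action is appended to a session record with its full
effective parameter set (defaults included), any RNG seed, and SHA-256
digests of inputs and outputs. The machine file is YAML data, not an
executable script — replay re-runs the pipeline through the library, so
loading a session can never execute code; a converter to an equivalent
shell-command listing exists for communication. Replay verifies input
digests before running and output digests after; with explicit parameter
overrides the divergence is reported instead, and a fresh session is
written. Timestamps are recorded but excluded from equivalence
comparisons, as they are the one legitimately run-varying field.

## The synthetic test inputs

`mdprep.fixtures` generates everything the tests consume: a mini force
field (water; glycine-, alanine-, cysteine-, aspartate-like residues; a
histidine-like tautomer trio built on a toy two-nitrogen side chain; Na⁺
and Cl⁻; amino/carboxy terminal patches; an acid-protonation patch; a
two-target disulfide patch), extended-conformation toy peptides whose
heavy atoms are reconstructed from the force field's own IC records after
seeding three backbone atoms, a 64-water unit cell on a 4×4×4 lattice in
a 9.3 Å cube (O–O spacing 2.325 Å, hydrogens kept inside the cell so
tiling never leaks atoms), and NAMD-style energy-log text. All fixtures
are deterministic pure functions.

The fixture values are physically plausible (bonds 0.96–2.02 Å, angles
97–123°) but synthetic: charges are small round numbers arranged to make
residue totals exact, the histidine analog has no ring, and the water
cell is a lattice, not an equilibrated liquid. Passing tests therefore
demonstrate the *structural contracts* — parsing fidelity, graph
generation, IC geometry, charge bookkeeping, determinism — not
thermodynamic realism; real CHARMM36 files exercise identical code paths
with more records per residue.

## Problem sizes and verification

The shipped verification (`scripts/acceptance.py` and the test suite)
runs at deliberately small scale: 3–4-residue peptides, boxes of 500–2500
waters, 50 random bond graphs of ≤9 atoms, 1000 random IC frames. These
sizes were chosen because every checked property (counting rules, exact
neutrality, byte-identical reruns, boundary location at 45°) is
scale-free; nothing about the checks would change at protein scale beyond
runtime. The PDB writer switches atom serials to hexadecimal past 99,999
atoms so half-million-atom systems remain single-file representable;
resids beyond 9999 are an error rather than a silent truncation.

## Known limitations

No rotamer search or clash-aware side-chain placement (IC defaults only);
no loop building for missing residues; no pKa prediction behind
protonation choices; no lipid-bilayer construction (the membrane
environment is supported at the config level only); no mmCIF input or
symmetry expansion; the engine itself is never executed.
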