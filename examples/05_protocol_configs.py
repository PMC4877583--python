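"""Protocol generation: environment-aware NAMD-style configuration files.

Shows the default minimization/annealing/equilibration/production ladder
for explicit solvent, the per-environment electrostatics choices, and a
steered-MD (constant-velocity pulling) setup.
"""

from mdprep.fixtures import build_toy_peptide, mini_topology_set
from mdprep.protocol import (
    EnvironmentSpec,
    ProtocolStage,
    default_protocol,
    generate_config,
    setup_smd,
)

explicit = EnvironmentSpec(kind="explicit", box=(40.0, 40.0, 40.0))
stages = default_protocol(explicit, target_temperature=300.0)
print("stage ladder:", " -> ".join(f"{s.name}({s.steps} steps)" for s in stages))
# annealing + equilibration span 500,000 steps = 1 ns at the 2 fs timestep

files = {"structure": "s.psf", "coordinates": "s.pdb", "restraints": "r.pdb"}
doc = generate_config(stages[-1], explicit, files)
for key in ("cutoff", "timestep", "fullElectFrequency", "PME"):
    print(f"  explicit production: {key} = {doc.get(key)}")

for kind in ("vacuum", "implicit"):
    env = EnvironmentSpec(kind=kind)
    doc = generate_config(default_protocol(env)[-1], env, files)
    elec = ("dielectric " + doc.get("dielectric")) if doc.has("dielectric") else "GBIS"
    print(f"  {kind}: periodic cell off, electrostatics via {elec}")

# SMD: pull residue 3 away from residue 1 along their centroid axis
topo = mini_topology_set()
peptide = build_toy_peptide(3, topo=topo)
spec, _reference_pdb = setup_smd(
    peptide, "resid:P:1", "resid:P:3", velocity=2.5, spring_k=7.0,
)
print(f"SMD direction {tuple(round(v, 3) for v in spec.direction)} "
      f"(unit vector anchor->pull), v = {spec.velocity} A/ns, "
      f"k = {spec.spring_k} kcal/mol/A^2")
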