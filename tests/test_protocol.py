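"""Config generation: environment matrix, stage ladder, restraints, SMD."""

import numpy as np
import pytest

from mdprep.fixtures import build_toy_peptide
from mdprep.protocol import (
    DEFAULTS,
    EnvironmentSpec,
    ProtocolError,
    ProtocolStage,
    SMDSpec,
    default_protocol,
    generate_config,
    parse_config_text,
    select_atoms,
    setup_smd,
    write_restraint_reference,
)
from mdprep.system_model import read_pdb

EXPLICIT = EnvironmentSpec(kind="explicit", box=(40.0, 40.0, 40.0))
MEMBRANE = EnvironmentSpec(kind="membrane", box=(40.0, 40.0, 40.0), constant_area=True)
VACUUM = EnvironmentSpec(kind="vacuum")
IMPLICIT = EnvironmentSpec(kind="implicit", salt=0.15)

FILES = {"structure": "s.psf", "coordinates": "s.pdb", "restraints": "r.pdb"}


def _production(env):
    stages = default_protocol(env)
    return generate_config(stages[-1], env, FILES)


@pytest.mark.parametrize(
    "env, periodic, electrostatics, constant_area",
    [
        (VACUUM, False, "cutoff", None),
        (IMPLICIT, False, "GBIS", None),
        (EXPLICIT, True, "PME", None),
        (MEMBRANE, True, "PME", "on"),
    ],
    ids=["vacuum", "implicit", "explicit", "membrane"],
)
def test_environment_matrix_golden(env, periodic, electrostatics, constant_area):
    """Each environment emits its (PBC, electrostatics, constant-area) triple."""
    doc = _production(env)
    assert doc.has("cellBasisVector1") == periodic
    assert doc.has("cellOrigin") == periodic
    if electrostatics == "PME":
        assert doc.get("PME") == "on"
        assert not doc.has("GBIS") and not doc.has("dielectric")
    elif electrostatics == "GBIS":
        assert doc.get("GBIS") == "on"
        assert not doc.has("PME") and not doc.has("dielectric")
    else:
        assert doc.get("dielectric") == "80"
        assert not doc.has("PME") and not doc.has("GBIS")
    if constant_area is None:
        assert not doc.has("useConstantArea")
    else:
        assert doc.get("useConstantArea") == constant_area


def test_explicit_config_core_constants():
    doc = _production(EXPLICIT)
    assert doc.get("cutoff") == "12"
    assert doc.get("timestep") == "2"
    assert doc.get("fullElectFrequency") == "2"
    assert doc.get("nonbondedFreq") == "1"
    assert doc.get("switchdist") == "10"


def test_vacuum_config_has_no_barostat():
    stages = default_protocol(VACUUM)
    for stage in stages:
        doc = generate_config(stage, VACUUM, FILES)
        assert not doc.has("langevinPiston")
        assert not doc.has("cellBasisVector1")


def test_default_protocol_ladder_and_step_budget():
    stages = default_protocol(EXPLICIT, target_temperature=300.0)
    assert [s.kind for s in stages] == [
        "minimization", "annealing", "equilibration", "production",
    ]
    # annealing + equilibration cover 1 ns at a 2 fs timestep
    assert stages[1].steps + stages[2].steps == 500_000
    assert stages[1].temperature_start < stages[1].temperature_end == 300.0
    assert stages[1].restrained and stages[2].restrained
    assert not stages[3].restrained


def test_stage_configs_chain_previous_output():
    stages = default_protocol(EXPLICIT)
    prev = None
    for stage in stages:
        files = dict(FILES, output=stage.name)
        if prev is not None:
            files["previous_output"] = prev.name
        doc = generate_config(stage, EXPLICIT, files, previous_stage=prev)
        if prev is not None:
            assert doc.get("binCoordinates") == f"{prev.name}.coor"
        prev = stage


def test_annealing_schedule_reaches_target_in_fixed_increments():
    stages = default_protocol(EXPLICIT, target_temperature=300.0)
    ann = stages[1]
    doc = generate_config(ann, EXPLICIT, FILES)
    incr = float(doc.get("reassignIncr"))
    freq = int(doc.get("reassignFreq"))
    assert incr == DEFAULTS["annealing_increment"]
    start, hold = float(doc.get("reassignTemp")), float(doc.get("reassignHold"))
    n_steps_needed = int(np.ceil((hold - start) / incr)) * freq
    assert start == ann.temperature_start and hold == 300.0
    assert n_steps_needed <= ann.steps


def test_restrained_stage_requires_reference_file():
    stages = default_protocol(EXPLICIT)
    with pytest.raises(ProtocolError, match="restraint"):
        generate_config(stages[1], EXPLICIT, {"structure": "s.psf", "coordinates": "s.pdb"})
    doc = generate_config(stages[1], EXPLICIT, FILES)
    assert doc.get("consref") == "r.pdb"
    assert doc.get("conskcol") == "B"


def test_config_round_trips_through_text():
    for env in (VACUUM, IMPLICIT, EXPLICIT, MEMBRANE):
        for stage in default_protocol(env):
            doc = generate_config(stage, env, FILES)
            assert parse_config_text(doc.to_text()) == doc


def test_environment_validation():
    with pytest.raises(ProtocolError, match="box"):
        EnvironmentSpec(kind="explicit")
    with pytest.raises(ProtocolError, match="membrane"):
        EnvironmentSpec(kind="explicit", box=(1, 1, 1), constant_area=True)
    with pytest.raises(ProtocolError):
        ProtocolStage(kind="production", name="p", steps=0,
                      temperature_start=300, temperature_end=300)
    with pytest.raises(ProtocolError, match="ramp"):
        ProtocolStage(kind="production", name="p", steps=10,
                      temperature_start=300, temperature_end=310)


# ---------------------------------------------------------------------------
# Restraint reference
# ---------------------------------------------------------------------------

def test_restraint_reference_marks_exactly_backbone(peptide):
    k = 2.0
    text = write_restraint_reference(peptide, "backbone", k)
    records = read_pdb(text).records
    expected = {i for i in select_atoms(peptide, "backbone")}
    for i, rec in enumerate(records):
        assert rec.bfactor == pytest.approx(k if i in expected else 0.0)
    assert 0 < len(expected) < len(records)


def test_restraint_reference_empty_selection_all_zero(peptide):
    text = write_restraint_reference(peptide, "none", 2.0)
    assert all(r.bfactor == 0.0 for r in read_pdb(text).records)


def test_restraint_k_zero_equivalent_to_unrestrained(peptide):
    text = write_restraint_reference(peptide, "backbone", 0.0)
    assert all(r.bfactor == 0.0 for r in read_pdb(text).records)


# ---------------------------------------------------------------------------
# SMD
# ---------------------------------------------------------------------------

def test_smd_direction_is_unit_vector_between_centroids(peptide):
    spec, _ = setup_smd(
        peptide, "resid:P:1", "resid:P:3", velocity=2.5, spring_k=7.0,
    )
    coords = peptide.coordinates()
    a = coords[select_atoms(peptide, "resid:P:1")].mean(axis=0)
    p = coords[select_atoms(peptide, "resid:P:3")].mean(axis=0)
    expected = (p - a) / np.linalg.norm(p - a)
    assert np.allclose(spec.direction, expected, atol=1e-12)
    assert np.linalg.norm(spec.direction) == pytest.approx(1.0)


def test_smd_rejects_overlapping_or_empty_selections(peptide):
    with pytest.raises(ProtocolError, match="overlap"):
        setup_smd(peptide, "resid:P:1", "resid:P:1-2", velocity=1.0)
    with pytest.raises(ProtocolError, match="non-empty"):
        setup_smd(peptide, "none", "resid:P:3", velocity=1.0)


def test_smd_parameters_pass_through_to_config(peptide):
    spec, ref_text = setup_smd(peptide, "resid:P:1", "resid:P:3",
                               velocity=2.5, spring_k=7.0)
    stage = ProtocolStage(
        kind="smd", name="smd", steps=1000,
        temperature_start=300.0, temperature_end=300.0, smd=spec,
    )
    doc = generate_config(stage, EXPLICIT, dict(FILES, smdfile="smd.pdb"))
    assert doc.get("SMDVel") == "2.5"
    assert doc.get("SMDk") == "7"
    assert doc.get("SMDFile") == "smd.pdb"
    # reference file: anchors fixed via occupancy, pull atoms tagged in B
    records = read_pdb(ref_text).records
    anchors = set(select_atoms(peptide, "resid:P:1"))
    pulls = set(select_atoms(peptide, "resid:P:3"))
    for i, rec in enumerate(records):
        assert rec.occupancy == pytest.approx(1.0 if i in anchors else 0.0)
        assert rec.bfactor == pytest.approx(1.0 if i in pulls else 0.0)
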