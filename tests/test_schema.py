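"""Model-definition validation, koff derivation and pairing enumeration."""

import pytest
from hypothesis import given, strategies as st

from synapsim import presets
from synapsim.schema import (
    CellTypeSpec,
    DrugArmSpec,
    ModelDefinition,
    ReceptorSpec,
    SynapsePairing,
    ValidationError,
    definition_from_dict,
    definition_to_dict,
    derive_koff,
    enumerate_pairings,
    load_model_definition,
    save_model_definition,
)
from oracles import brute_force_pairings


@pytest.mark.parametrize("kon,KD,expected", [
    (0.1, 1.0, 0.1),
    (2.0, 0.5, 1.0),
    (0.0, 5.0, 0.0),  # disabled arm: kon 0 gives koff 0
])
def test_derive_koff(kon, KD, expected):
    assert derive_koff(kon, KD) == expected


@pytest.mark.parametrize("kon,KD", [(-0.1, 1.0), (0.1, 0.0), (0.1, -2.0)])
def test_derive_koff_rejects_bad_domain(kon, KD):
    with pytest.raises(ValueError):
        derive_koff(kon, KD)


@given(kon=st.floats(0, 1e3, allow_nan=False),
       KD=st.floats(1e-6, 1e4, allow_nan=False))
def test_koff_consistency_on_arms(kon, KD):
    """|koff - KD*kon| is exactly zero for any constructed arm."""
    arm = DrugArmSpec("X", kon=kon, KD=KD)
    assert arm.koff == KD * kon


def _toy_definition(cell_receptors, arms=None):
    arms = arms or {"CD3": "A", "CD28": "B", "CD38": "C"}
    used = sorted({r for rs in cell_receptors.values() for r in rs})
    cells = [CellTypeSpec(name, "tumor", receptors=list(rs), killable=False)
             for name, rs in cell_receptors.items()]
    receptors = [ReceptorSpec(r, {c: 1.0 for c, rs in cell_receptors.items() if r in rs},
                              arms[r]) for r in used]
    arm_specs = [DrugArmSpec(a, kon=0.1, KD=1.0) for a in sorted({arms[r] for r in used})]
    return ModelDefinition(name="toy", cells=cells, receptors=receptors,
                           arms=arm_specs).validate()


def test_full_model_loads_with_expected_structure():
    defn = presets.trispecific_definition()
    assert len(defn.cells) == 8
    assert sorted(r.name for r in defn.receptors) == ["CD28", "CD3", "CD38"]
    assert len(defn.arms) == 3
    # CD38 is not expressed on T cells by default
    assert all(not c.endswith(("naive", "EM", "active"))
               for c in defn.receptor("CD38").expressed_on)


def test_validation_reports_every_dangling_reference():
    doc = definition_to_dict(presets.minimal_definition())
    doc["cells"][0]["receptors"].append("CD99")  # undeclared receptor
    doc["receptors"][0]["expressed_on"]["ghost"] = 5.0  # undeclared cell
    with pytest.raises(ValidationError) as err:
        definition_from_dict(doc)
    msg = str(err.value)
    assert "CD99" in msg and "ghost" in msg


def test_round_trip_is_identity(tmp_path):
    defn = presets.trispecific_definition()
    path = tmp_path / "model.yaml"
    save_model_definition(defn, path)
    again = load_model_definition(path)
    assert definition_to_dict(again) == definition_to_dict(defn)
    # and a second round trip through JSON
    jpath = tmp_path / "model.json"
    save_model_definition(again, jpath)
    assert definition_to_dict(load_model_definition(jpath)) == definition_to_dict(defn)


def test_enumeration_matches_brute_force_oracle():
    """Enumeration equals exhaustive search on assorted <=4-cell definitions."""
    cases = [
        {"T": ["CD3", "CD28"], "M": ["CD38", "CD28"]},
        {"T": ["CD3", "CD28"], "M": ["CD38", "CD28"], "P": ["CD38"]},
        {"A": ["CD3"], "B": ["CD3"]},  # same arm only: nothing bridges
        {"A": ["CD3"], "B": ["CD28"], "C": ["CD38"], "D": ["CD3", "CD38"]},
        {"solo": ["CD3"]},
    ]
    for cell_receptors in cases:
        defn = _toy_definition(cell_receptors)
        got = {(p.cell_a, p.receptor_a, p.cell_b, p.receptor_b)
               for p in enumerate_pairings(defn)}
        arms = {r.name: r.drug_arm for r in defn.receptors}
        expected = brute_force_pairings(cell_receptors, arms)
        assert got == expected


def test_enumeration_is_order_invariant():
    defn = presets.trispecific_definition()
    forward = enumerate_pairings(defn)
    reversed_defn = ModelDefinition(
        name=defn.name, cells=list(reversed(defn.cells)),
        receptors=list(reversed(defn.receptors)), arms=defn.arms,
        cytokines=defn.cytokines, soluble_antigen=defn.soluble_antigen,
        activation=defn.activation, killing=defn.killing,
        resistance_rate=defn.resistance_rate,
        collision_factor=defn.collision_factor,
        bridges_per_synapse=defn.bridges_per_synapse,
        volume=defn.volume, reference_volume=defn.reference_volume,
    ).validate()
    assert enumerate_pairings(reversed_defn) == forward


def test_full_model_pairing_content():
    defn = presets.trispecific_definition()
    pairs = enumerate_pairings(defn)
    keys = {p.key for p in pairs}
    # T--T via CD3/CD28, T--MM via all three distinct-arm routes, MM--PBMC
    assert "CD4_EM:CD3|CD4_naive:CD28" in keys
    assert "CD4_naive:CD3|MM:CD38" in keys
    assert "CD4_naive:CD3|MM:CD28" in keys
    assert "CD4_naive:CD28|MM:CD38" in keys
    assert "MM:CD28|PBMC:CD38" in keys
    # no pairing bridges two copies of the same arm's target
    for p in pairs:
        assert defn.receptor(p.receptor_a).drug_arm != defn.receptor(p.receptor_b).drug_arm
    # PBMC--PBMC (CD38 only on both sides) is impossible
    assert not any(p.cell_a == "PBMC" and p.cell_b == "PBMC" for p in pairs)


def test_removing_cd28_arm_removes_shared_antigen_pairings():
    """Without the CD28 arm no T--T, MM--MM or MM--PBMC bridges exist."""
    doc = definition_to_dict(presets.trispecific_definition())
    doc["arms"] = [a for a in doc["arms"] if a["name"] != "CD28"]
    doc["receptors"] = [r for r in doc["receptors"] if r["name"] != "CD28"]
    for c in doc["cells"]:
        c["receptors"] = [r for r in c["receptors"] if r != "CD28"]
    defn = definition_from_dict(doc)
    t_names = {c.name for c in defn.cells if c.lineage.endswith("-T")}
    for p in enumerate_pairings(defn):
        sides = {p.cell_a, p.cell_b}
        assert not sides <= t_names, "T--T pairing should be impossible"
        assert sides != {"MM"}, "MM--MM pairing should be impossible"
        assert sides != {"MM", "PBMC"}, "MM--PBMC pairing should be impossible"


def test_explicit_pairing_allowlist_restricts_enumeration():
    defn = presets.minimal_definition()
    assert len(enumerate_pairings(defn)) == 1
    defn.pairings = []
    assert enumerate_pairings(defn) == []
    defn.pairings = [SynapsePairing.make("T", "CD3", "MM", "CD38")]
    assert len(enumerate_pairings(defn)) == 1


def test_pairing_canonical_ordering():
    a = SynapsePairing.make("T", "CD3", "MM", "CD38")
    b = SynapsePairing.make("MM", "CD38", "T", "CD3")
    assert a == b
    assert (a.cell_a, a.receptor_a) <= (a.cell_b, a.receptor_b)


def test_tumor_cells_cannot_kill():
    doc = definition_to_dict(presets.minimal_definition())
    for c in doc["cells"]:
        if c["name"] == "MM":
            c["can_kill"] = True
    with pytest.raises(ValidationError):
        definition_from_dict(doc)
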