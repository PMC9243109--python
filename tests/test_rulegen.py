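"""Structural and numerical correctness of the rule-based ODE generator."""

import numpy as np
import pytest

from synapsim import presets
from synapsim.rulegen import (
    GenerationError,
    count_model,
    generate_model,
    initial_state,
    rhs_evaluate,
)
from synapsim.schema import (
    CytokineProducer,
    CytokineSpec,
    ModelDefinition,
    definition_from_dict,
    definition_to_dict,
)
from oracles import MINIMAL_LINEAGES, MINIMAL_SPECIES, minimal_rhs


def test_minimal_species_match_hand_enumeration(minimal_model):
    """The generated species set equals the enumeration written out by hand:
    two free pools, one synapse, free/drug-bound receptor copies on each of
    the four contexts, and free drug."""
    assert [s.name for s in minimal_model.species] == MINIMAL_SPECIES
    assert [ln.name for ln in minimal_model.lineages] == MINIMAL_LINEAGES
    assert count_model(minimal_model) == {"n_species": 12, "n_parameters": 19}


def test_generation_errors_on_degenerate_definitions():
    doc = definition_to_dict(presets.minimal_definition())
    empty_cells = dict(doc, cells=[], receptors=[])
    with pytest.raises(GenerationError):
        generate_model(definition_from_dict(empty_cells))
    no_arms = definition_to_dict(presets.minimal_definition())
    no_arms["arms"] = []
    no_arms["receptors"] = []
    for c in no_arms["cells"]:
        c["receptors"] = []
    with pytest.raises(GenerationError):
        generate_model(definition_from_dict(no_arms))


def test_rhs_matches_hand_coded_oracle(minimal_model, rng):
    """Generated RHS equals an independently hand-coded RHS of the minimal
    model at 100 random non-negative states (relative agreement 1e-12)."""
    m = minimal_model
    p = m.default_params()
    p[m.param_index("dose")] = 0.05
    pdict = {prm.name: p[i] for i, prm in enumerate(m.parameters)}
    scales = np.array([1e10, 1e5, 1e4, 1e3, 1e9, 1e8, 1e9, 1e8,
                       1e7, 1e6, 1e7, 1e6] + [1e6] * 10)
    worst = 0.0
    for _ in range(100):
        x = rng.random(m.n_states) * scales
        got = rhs_evaluate(m, x, p)
        want = minimal_rhs(x, pdict)
        denom = np.maximum(np.abs(want), 1.0)
        worst = max(worst, float(np.max(np.abs(got - want) / denom)))
    assert worst < 1e-12


def test_zero_drug_silences_synapse_formation(minimal_model, rng):
    """With no drug anywhere (free or bound) every synapse-formation term is
    zero: free cells only decay/proliferate and no synapse can appear."""
    m = minimal_model
    p = m.default_params()
    x = initial_state(m, p, dose_nM=0.0)
    dx = rhs_evaluate(m, x, p)
    assert dx[m.species_index("syn.MM:CD38|T:CD3")] == 0.0
    # random drug-free states: bound pools and drug zero, the rest arbitrary
    for _ in range(10):
        x = rng.random(m.n_states) * 1e6
        for name in ("drug", "rec.CD3.bound@cell.T", "rec.CD38.bound@cell.MM",
                     "rec.CD3.bound@syn.MM:CD38|T:CD3#T",
                     "rec.CD38.bound@syn.MM:CD38|T:CD3#MM"):
            x[m.species_index(name)] = 0.0
        syn0 = x[m.species_index("syn.MM:CD38|T:CD3")] = 0.0
        dx = rhs_evaluate(m, x, p)
        assert dx[m.species_index("syn.MM:CD38|T:CD3")] == syn0


def test_lineage_bookkeeping_closes_at_the_rhs_level(full_model, rng):
    """For arbitrary random states, the derivative of each lineage total
    equals the registered synthesis-minus-degradation flux derivative: the
    term-by-term bookkeeping sums to zero within every conserved lineage."""
    m = full_model
    p = m.default_params()
    p[m.param_index("dose")] = 0.1
    for _ in range(5):
        x = rng.random(m.n_states) * 1e6
        dx = rhs_evaluate(m, x, p)
        for ln in m.lineages:
            w = m.lineage_weights(ln.name, p)
            total_dot = w @ dx[: m.n_species]
            flux_dot = dx[m.flux_index(ln.name, "synth")] - dx[m.flux_index(ln.name, "deg")]
            scale = max(abs(total_dot), abs(flux_dot), 1.0)
            assert abs(total_dot - flux_dot) / scale < 1e-10, ln.name


def test_dimension_mismatch_raises(minimal_model):
    m = minimal_model
    with pytest.raises(ValueError):
        rhs_evaluate(m, np.zeros(m.n_states - 1), m.default_params())
    with pytest.raises(ValueError):
        rhs_evaluate(m, np.zeros(m.n_states), np.zeros(m.n_parameters + 2))


def test_removing_a_pairing_never_increases_species_count():
    defn = presets.trispecific_definition()
    base = generate_model(defn)
    from synapsim.schema import enumerate_pairings

    all_pairs = enumerate_pairings(defn)
    for drop in (0, len(all_pairs) // 2, len(all_pairs) - 1):
        defn.pairings = all_pairs[:drop] + all_pairs[drop + 1:]
        reduced = generate_model(defn)
        assert reduced.n_species < base.n_species
    defn.pairings = None


def test_cytokine_producer_adds_exactly_its_rate_constants():
    defn = presets.trispecific_definition()
    n0 = generate_model(defn).n_parameters
    defn.cytokines.append(
        CytokineSpec("IL2", [CytokineProducer("CD8_active", 100.0)]))
    n1 = generate_model(defn).n_parameters
    assert n1 - n0 == 1  # one new (producer, cytokine) rate constant


def test_parameter_manifest_covers_expected_families(full_model):
    names = {p.name for p in full_model.parameters}
    for arm in ("CD3", "CD28", "CD38"):
        assert {f"kon.{arm}", f"KD.{arm}", f"koff.{arm}"} <= names
    assert "bridges_per_synapse" in names and "k_res" in names
    assert sum(n.startswith("collision.") for n in names) == 36
    assert sum(n.startswith("R.") for n in names) == 17
    assert sum(n.startswith("N0.") for n in names) == 9
    assert sum(n.startswith("k_cyt.") for n in names) == 8


def test_koff_zero_follows_kon_zero_in_generated_parameters():
    from synapsim.compare import make_bispecific

    defn = make_bispecific(presets.trispecific_definition())
    m = generate_model(defn)
    p = m.default_params()
    assert p[m.param_index("kon.CD28")] == 0.0
    assert p[m.param_index("koff.CD28")] == 0.0


def test_manifest_and_equation_listing_are_complete(minimal_model):
    man = minimal_model.to_manifest()
    assert man["n_species"] == 12 and man["n_parameters"] == 19
    assert len(man["species"]) == 12
    rules = {t["rule"] for t in man["terms"]}
    assert {"drug-binding", "synapse-formation", "synapse-dissociation",
            "proliferation", "degradation"} <= rules
    listing = minimal_model.equation_listing()
    for s in MINIMAL_SPECIES:
        assert f"d({s})/dt" in listing
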