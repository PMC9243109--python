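"""Bispecific variant construction, synapse classification and dose study."""

import numpy as np
import pandas as pd
import pytest

from synapsim import presets
from synapsim.compare import (
    DoseResponseTable,
    classify_synapses,
    compare_bi_tri,
    dose_response_study,
    free_active_t,
    is_bell,
    is_plateau,
    make_bispecific,
    total_active_t,
)
from synapsim.rulegen import generate_model, syn_name
from synapsim.schema import definition_to_dict
from synapsim.simulate import ExperimentSetup, check_flux_balance, receptor_occupancy, simulate


def test_make_bispecific_changes_exactly_one_definition_entry():
    tri = presets.trispecific_definition()
    bi = make_bispecific(tri)
    d_tri, d_bi = definition_to_dict(tri), definition_to_dict(bi)
    diffs = [(a, b) for a, b in zip(d_tri["arms"], d_bi["arms"]) if a != b]
    assert len(diffs) == 1
    assert diffs[0][1]["name"] == "CD28" and diffs[0][1]["kon"] == 0.0
    d_tri.pop("arms"), d_bi.pop("arms")
    assert d_tri == d_bi  # nothing but the arm changed
    assert bi.arm("CD28").koff == 0.0  # koff follows KD * kon


def test_make_bispecific_is_idempotent_and_validates():
    bi = make_bispecific(presets.trispecific_definition())
    again = make_bispecific(bi)
    assert definition_to_dict(bi) == definition_to_dict(again)
    with pytest.raises(ValueError):
        make_bispecific(presets.minimal_definition())  # no CD28 arm


def test_bispecific_shared_antigen_synapses_stay_empty(reduced_model):
    """kon_CD28 = 0 keeps every T--T, MM--MM and MM--PBMC synapse at exactly
    zero and CD28 receptor occupancy identically zero for all times."""
    bi = generate_model(make_bispecific(presets.reduced_blood_definition()))
    traj = simulate(bi, None, ExperimentSetup(dose=0.1, duration=48.0))
    cv = {c.name: c for c in bi.cells}
    touched = 0
    for p in bi.pairings:
        la, lb = cv[p.cell_a].lineage, cv[p.cell_b].lineage
        tt = la.endswith("-T") and lb.endswith("-T")
        mm = la == "tumor" and lb == "tumor"
        mp = {la, lb} == {"tumor", "PBMC"}
        if tt or mm or mp:
            touched += 1
            assert np.all(traj.series(syn_name(p)) == 0.0), p.key
    assert touched > 0
    for cell in ("CD8_naive", "CD8_EM", "CD8_active", "MM"):
        assert np.all(receptor_occupancy(traj, "CD28", cell) == 0.0)


def test_classification_rules_structural(reduced_model):
    m = reduced_model
    cls_tri = classify_synapses(m, trajectory=None, bispecific=False)
    cls_bi = classify_synapses(m, trajectory=None, bispecific=True)
    for p in m.pairings:
        cells = {p.cell_a, p.cell_b}
        key = syn_name(p)
        if "MM" not in cells and "MM_res" not in cells:
            assert not cls_tri[key], "non-tumor synapses are never effective"
        if cells == {"MM", "MM_res"} or cells == {"MM", "PBMC"}:
            assert not cls_tri[key]
        if "CD8_active" in cells and ("MM" in cells or "MM_res" in cells):
            assert cls_tri[key], "active-T--MM synapses are effective"
        # bispecific: a synapse whose only T member is naive cannot lead to
        # activation (no co-stimulation exists), hence is ineffective
        if "CD8_naive" in cells and not ({"CD8_EM", "CD8_active"} & cells):
            assert not cls_bi[key]


def test_classification_conditional_on_occupancy(reduced_model):
    """EM-T--MM synapses bridged through CD3 count as effective only when
    the T cell carries drug on both CD3 and CD28."""
    m = reduced_model
    traj = simulate(m, None, ExperimentSetup(dose=0.1, duration=24.0))
    cls = classify_synapses(m, traj, bispecific=False)
    em_cd3_keys = [syn_name(p) for p in m.pairings
                   for mem, rec, other in [(p.cell_a, p.receptor_a, p.cell_b),
                                           (p.cell_b, p.receptor_b, p.cell_a)]
                   if mem == "CD8_EM" and rec == "CD3" and other in ("MM", "MM_res")]
    assert em_cd3_keys and all(cls[k] for k in em_cd3_keys)
    # at dose zero there is no occupancy, so the conditional rule rejects
    ctrl = simulate(m, None, ExperimentSetup(dose=0.0, duration=24.0))
    cls0 = classify_synapses(m, ctrl, bispecific=False)
    assert not any(cls0[k] for k in em_cd3_keys)


def test_effective_plus_ineffective_equals_total(reduced_model):
    from synapsim.compare import _synapse_totals

    m = reduced_model
    traj = simulate(m, None, ExperimentSetup(dose=0.3, duration=24.0))
    eff, ineff = _synapse_totals(m, traj, classify_synapses(m, traj))
    total = sum(traj.series(syn_name(p)) for p in m.pairings)
    assert np.allclose(eff + ineff, total, rtol=0, atol=1e-9)


def test_dose_response_study_validates_grid(reduced_model):
    defn = presets.reduced_blood_definition()
    with pytest.raises(ValueError):
        dose_response_study(defn, None, doses=[], model=reduced_model)
    with pytest.raises(ValueError):
        dose_response_study(defn, None, doses=[0.1, 0.1], model=reduced_model)


def test_compare_bi_tri_identity_and_grid_mismatch():
    doses = [0.01, 0.1, 1.0]
    frame = pd.DataFrame({"dose_nM": doses, "pct_killing_mean": [10.0, 40.0, 60.0]})
    t = DoseResponseTable("trispecific", frame)
    b = DoseResponseTable("bispecific", frame.copy())
    summary = compare_bi_tri(t, b)
    assert np.allclose(summary.fold_advantage["ratio"], 1.0)
    b2 = DoseResponseTable("bispecific", frame.assign(dose_nM=[0.01, 0.2, 1.0]))
    with pytest.raises(ValueError):
        compare_bi_tri(t, b2)


def test_shape_detectors():
    doses = np.logspace(-3, 1, 9)
    plateau = np.array([0, 5, 20, 50, 80, 90, 92, 91, 90.5])
    bell = np.array([0, 5, 20, 50, 80, 90, 70, 40, 20])
    assert is_plateau(doses, plateau) and not is_bell(doses, plateau)
    assert is_bell(doses, bell) and not is_plateau(doses, bell)


def test_expression_downregulation_scenario_preserves_invariants(reduced_model):
    """Receptor-downregulation what-if runs as a parameter override and keeps
    flux closure and occupancy bounds intact."""
    m = reduced_model
    p = m.params_with({"R.CD38.MM": presets.CD38_HIGH * 0.2,
                       "R.CD28.CD8_EM": presets.EXPRESSION["CD28_T"] * 0.5})
    traj = simulate(m, p, ExperimentSetup(dose=0.1, duration=24.0))
    assert check_flux_balance(traj, tol=1e-6).passed
    ro = receptor_occupancy(traj, "CD38", "MM")
    assert np.all((0 <= ro) & (ro <= 1))
    assert np.all(total_active_t(traj) >= free_active_t(traj) - 1e-9)
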