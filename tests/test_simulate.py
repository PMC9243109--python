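"""Integration, flux audit, occupancy and killing readouts."""

import numpy as np
import pytest

from synapsim import presets
from synapsim.rulegen import generate_model
from synapsim.compare import classify_synapses
from synapsim.simulate import (
    ExperimentSetup,
    cell_state_distribution,
    check_flux_balance,
    effective_receptor_occupancy,
    percent_killing,
    receptor_occupancy,
    simulate,
    trajectory_to_frame,
)


def test_zero_dose_matches_exponential_closed_form(minimal_model):
    """Without drug each free pool follows N0*exp((k_prolif-k_deg)t) and no
    synapse ever forms."""
    m = minimal_model
    traj = simulate(m, None, ExperimentSetup(dose=0.0, duration=72.0))
    p = traj.params
    for cell in ("T", "MM"):
        n0 = p[m.param_index(f"N0.{cell}")]
        net = p[m.param_index(f"k_prolif.{cell}")] - p[m.param_index(f"k_deg.{cell}")]
        expect = n0 * np.exp(net * traj.t)
        got = traj.series(f"cell.{cell}")
        assert np.max(np.abs(got - expect) / expect) < 1e-6
    assert np.all(traj.series("syn.MM:CD38|T:CD3") == 0.0)


def test_high_dose_reaches_quasi_steady_state_faster(minimal_model):
    """Low doses give slower kinetics; a high dose reaches 90% of its final
    synapse level earlier in the run."""
    m = minimal_model

    def t90(dose):
        traj = simulate(m, None, ExperimentSetup(dose=dose, duration=72.0))
        syn = traj.series("syn.MM:CD38|T:CD3")
        target = 0.9 * syn[-1]
        return traj.t[np.argmax(syn >= target)]

    assert t90(0.672) < t90(8.4e-4)


def test_tolerance_refinement_is_converged(minimal_model):
    m = minimal_model
    setup = ExperimentSetup(dose=0.05, duration=48.0)
    a = simulate(m, None, setup, rtol=1e-8, atol=1e-6)
    b = simulate(m, None, setup, rtol=0.5e-8, atol=0.5e-6)
    xa, xb = a.states[:, -1], b.states[:, -1]
    scale = np.maximum(np.abs(xa), 1.0)
    assert np.max(np.abs(xa - xb) / scale) < 1e-3


def test_flux_audit_passes_and_is_exact_at_t0(minimal_model):
    traj = simulate(minimal_model, None, ExperimentSetup(dose=0.1, duration=48.0))
    report = check_flux_balance(traj, tol=1e-6)
    assert report.passed, str(report)
    # at the t=0 snapshot the discrepancy is exactly zero
    for ln in minimal_model.lineages:
        total = minimal_model.lineage_total(ln.name, traj.states[:, :1], traj.params)
        synth = traj.states[minimal_model.flux_index(ln.name, "synth"), 0]
        deg = traj.states[minimal_model.flux_index(ln.name, "deg"), 0]
        assert total[0] - (total[0] + synth - deg) == 0.0


def test_fault_injection_breaks_the_tumor_lineage_audit():
    """Deliberately dropping one killing term's degradation bookkeeping must
    make the audit fail and implicate the tumor lineage."""
    model = generate_model(presets.cytotoxicity_stage_definition())
    killing_events = [t for t in model.terms
                      if t.rule == "killing" and any(k.startswith("cell.")
                                                     for k in t.stoich)]
    assert killing_events
    killing_events[0].flux = [f for f in killing_events[0].flux
                              if not f[0].startswith("cells.")]
    model._compiled = None
    traj = simulate(model, None, ExperimentSetup(dose=0.3, duration=24.0))
    report = check_flux_balance(traj, tol=1e-6)
    assert not report.passed
    failing = {a.lineage for a in report.lineages if not a.passed}
    assert "cells.tumor" in failing


def test_occupancy_bounds_and_ordering(reduced_model):
    """effective RO <= RO <= 1 for every receptor/cell pair over the run."""
    traj = simulate(reduced_model, None, ExperimentSetup(dose=0.1, duration=48.0))
    for receptor, cell in [("CD38", "MM"), ("CD28", "MM"), ("CD3", "CD8_EM"),
                           ("CD28", "CD8_naive"), ("CD38", "PBMC")]:
        ro = receptor_occupancy(traj, receptor, cell)
        ero = effective_receptor_occupancy(traj, receptor, cell)
        assert np.all(ro <= 1.0 + 1e-9)
        assert np.all(ero <= ro + 1e-12)
        assert np.all(ero >= -1e-12)


def test_occupancy_zero_dose_and_saturation(reduced_model):
    m = reduced_model
    traj0 = simulate(m, None, ExperimentSetup(dose=0.0, duration=24.0))
    assert np.all(receptor_occupancy(traj0, "CD38", "MM") == 0.0)
    traj = simulate(m, None, ExperimentSetup(dose=100.0, duration=24.0))
    assert receptor_occupancy(traj, "CD38", "MM")[-1] > 0.99


def test_occupancy_unknown_names_raise(reduced_model):
    traj = simulate(reduced_model, None, ExperimentSetup(dose=0.0, duration=1.0))
    with pytest.raises(KeyError):
        receptor_occupancy(traj, "CD5", "MM")
    with pytest.raises(KeyError):
        receptor_occupancy(traj, "CD38", "nosuchcell")


def test_percent_killing_identities(reduced_model):
    m = reduced_model
    ctrl = simulate(m, None, ExperimentSetup(dose=0.0, duration=24.0))
    assert np.allclose(percent_killing(ctrl, ctrl), 0.0)
    treated = simulate(m, None, ExperimentSetup(dose=0.3, duration=24.0))
    pk = percent_killing(treated, ctrl)
    assert pk[-1] > 0.0
    with pytest.raises(ValueError):
        percent_killing(treated, treated)  # control must be dose 0
    other = simulate(m, None, ExperimentSetup(dose=0.0, duration=12.0))
    with pytest.raises(ValueError):
        percent_killing(treated, other)  # mismatched duration


def test_cell_state_distribution_normalisation(reduced_model):
    m = reduced_model
    traj = simulate(m, None, ExperimentSetup(dose=0.1, duration=48.0))
    dist = cell_state_distribution(traj, classify_synapses(m, traj))
    for lineage, comp in dist.items():
        total = sum(comp.values())
        assert np.max(np.abs(total - 1.0)) < 1e-6, lineage
        for key, frac in comp.items():
            assert np.all(frac >= -1e-9) and np.all(frac <= 1.0 + 1e-9), (lineage, key)
    # at t=0 everything is free (inactive plus the configured pre-active pool)
    t0 = {lin: comp["free_inactive"][0] + comp["free_active"][0]
          for lin, comp in dist.items()}
    assert all(abs(v - 1.0) < 1e-9 for v in t0.values())


def test_simulation_failure_reports_last_valid_time(minimal_model):
    from synapsim.simulate import SimulationError

    m = minimal_model
    p = m.default_params()
    p[m.param_index("k_prolif.MM")] = 1e6  # absurd growth blows the solve up
    with pytest.raises((SimulationError, Exception)):
        simulate(m, p, ExperimentSetup(dose=0.1, duration=1000.0), rtol=1e-3,
                 atol=1e3)


def test_trajectory_frame_is_tidy(minimal_model):
    traj = simulate(minimal_model, None, ExperimentSetup(dose=0.01, duration=6.0))
    df = trajectory_to_frame(traj, species=["drug", "cell.T"])
    assert list(df.columns) == ["time_h", "species", "value"]
    assert set(df["species"]) == {"drug", "cell.T"}
    assert len(df) == 2 * len(traj.t)
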