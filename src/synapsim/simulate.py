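"""Integration of generated models and derived in vitro readouts.

The state vector couples species spanning ~12 orders of magnitude (cells,
receptor copies, drug molecules), with binding kinetics much faster than
lifecycle kinetics, so the default solver is stiff-capable (BDF) with an
analytic Jacobian sparsity pattern from the rule structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from .rulegen import GeneratedModel, initial_state, pool_name, syn_name

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-6
N_REPORT = 97


class SimulationError(RuntimeError):
    def __init__(self, message: str, last_valid_time: Optional[float] = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


@dataclass
class ExperimentSetup:
    """Description of one in vitro incubation."""

    dose: float  # nM
    duration: float  # hours
    volume: Optional[float] = None  # mL; None = definition volume
    initial_counts: dict[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        for cell, n in self.initial_counts.items():
            if n < 0:
                raise ValueError(f"negative initial count for {cell}")

    def replace(self, **kw) -> "ExperimentSetup":
        d = {"dose": self.dose, "duration": self.duration, "volume": self.volume,
             "initial_counts": dict(self.initial_counts), "label": self.label}
        d.update(kw)
        return ExperimentSetup(**d)


@dataclass
class Trajectory:
    t: np.ndarray  # hours, strictly increasing
    states: np.ndarray  # (n_states, n_times): species then flux accumulators
    params: np.ndarray
    setup: ExperimentSetup
    model: GeneratedModel
    diagnostics: dict = field(default_factory=dict)

    def series(self, species: str) -> np.ndarray:
        return self.states[self.model.species_index(species)]

    def final(self, species: str) -> float:
        return float(self.series(species)[-1])


def _resolve_params(model: GeneratedModel,
                    params: Union[np.ndarray, dict, None]) -> np.ndarray:
    if params is None:
        return model.default_params()
    if isinstance(params, dict):
        return model.params_with(params)
    p = np.asarray(params, dtype=float).copy()
    if p.shape != (model.n_parameters,):
        raise ValueError(
            f"parameter vector must have length {model.n_parameters}, got {p.shape}")
    return p


def simulate(model: GeneratedModel,
             params: Union[np.ndarray, dict, None],
             setup: ExperimentSetup,
             rtol: float = DEFAULT_RTOL,
             atol: float = DEFAULT_ATOL,
             method: str = "BDF",
             n_report: int = N_REPORT) -> Trajectory:
    """Integrate the model for one experiment.

    The reporting grid has ``n_report`` evenly spaced points over the run.
    Raises :class:`SimulationError` with the last valid time on failure.
    """
    p = _resolve_params(model, params)
    p[model.param_index("dose")] = setup.dose
    if setup.volume is not None:
        p[model.param_index("volume")] = setup.volume
    x0 = initial_state(model, p, counts=setup.initial_counts)
    compiled = model.compiled()
    rhs = compiled.bind(p)
    t_eval = np.linspace(0.0, setup.duration, n_report)
    kwargs = {}
    if method in ("BDF", "Radau", "LSODA"):
        kwargs["jac_sparsity"] = compiled.jac_sparsity()
    sol = solve_ivp(rhs, (0.0, setup.duration), x0, method=method,
                    t_eval=t_eval, rtol=rtol, atol=atol, **kwargs)
    if not sol.success:
        last = float(sol.t[-1]) if len(sol.t) else 0.0
        raise SimulationError(
            f"integration failed at t={last:.3f} h: {sol.message}", last_valid_time=last)
    diag = {"nfev": sol.nfev, "njev": sol.njev, "status": sol.status,
            "method": method, "rtol": rtol, "atol": atol}
    return Trajectory(t=sol.t, states=sol.y, params=p, setup=setup,
                      model=model, diagnostics=diag)


# ---------------------------------------------------------------------------
# flux-balance audit


@dataclass
class LineageAudit:
    lineage: str
    max_rel_discrepancy: float
    passed: bool


@dataclass
class FluxAuditReport:
    tol: float
    lineages: list[LineageAudit]

    @property
    def passed(self) -> bool:
        return all(a.passed for a in self.lineages)

    @property
    def worst(self) -> LineageAudit:
        return max(self.lineages, key=lambda a: a.max_rel_discrepancy)

    def __str__(self) -> str:
        lines = [f"flux audit (tol={self.tol:g}): "
                 f"{'PASS' if self.passed else 'FAIL'}"]
        for a in self.lineages:
            mark = "ok " if a.passed else "FAIL"
            lines.append(f"  [{mark}] {a.lineage:24s} max rel. discrepancy {a.max_rel_discrepancy:.3e}")
        return "\n".join(lines)


def check_flux_balance(trajectory: Trajectory, tol: float = 1e-6) -> FluxAuditReport:
    """Compare each conserved lineage's total against initial + net flux.

    For every lineage the weighted species total must equal the initial total
    plus accumulated synthesis minus accumulated degradation at every
    reported time.  Discrepancies are normalised by the running total (floor
    1) and reported, not raised.
    """
    model = trajectory.model
    out = []
    for ln in model.lineages:
        total = model.lineage_total(ln.name, trajectory.states, trajectory.params)
        synth = trajectory.states[model.flux_index(ln.name, "synth")]
        deg = trajectory.states[model.flux_index(ln.name, "deg")]
        audit = total[0] + synth - deg
        scale = np.maximum(np.abs(total), 1.0)
        disc = float(np.max(np.abs(total - audit) / scale))
        out.append(LineageAudit(ln.name, disc, disc < tol))
    return FluxAuditReport(tol=tol, lineages=out)


# ---------------------------------------------------------------------------
# receptor occupancy


def _select_cells(model: GeneratedModel, cell: str) -> list:
    """Resolve a pool name (includes its resistant shadow pool) or lineage."""
    views = [c for c in model.cells if c.lineage == cell]
    if views:
        return views
    views = [c for c in model.cells if c.name == cell or c.parent == cell]
    if not views:
        raise KeyError(f"unknown cell or lineage {cell!r}")
    return views


def _occupancy_weights(model: GeneratedModel, params, receptor: str, cell: str):
    """(bound, bridged, total) weight vectors over species for a receptor on
    a cell population, counting all contexts the population occupies."""
    cells = _select_cells(model, cell)
    names = {c.name for c in cells if receptor in c.receptors}
    if not names:
        raise KeyError(f"receptor {receptor!r} not expressed on {cell!r}")
    b = params[model.param_index("bridges_per_synapse")]
    n = model.n_species
    w_bound = np.zeros(n)
    w_bridged = np.zeros(n)
    w_free = np.zeros(n)
    for s in model.species:
        if s.kind != "receptor-state":
            continue
        # rec.<receptor>.<state>@<context>[#member]
        head, _, ctx = s.name.partition("@")
        _, rname, state = head.split(".")
        if rname != receptor:
            continue
        member = ctx.partition("#")[2]
        owner = member if member else ctx.removeprefix("cell.")
        if owner in names:
            (w_bound if state == "bound" else w_free)[model.species_index(s.name)] = 1.0
    for p in model.pairings:
        for mem, r in ((p.cell_a, p.receptor_a), (p.cell_b, p.receptor_b)):
            if mem in names and r == receptor:
                w_bridged[model.species_index(syn_name(p))] += b
    return w_bound, w_bridged, w_bound + w_bridged + w_free


def receptor_occupancy(trajectory: Trajectory, receptor: str, cell: str) -> np.ndarray:
    """Fraction of the receptor pool on a cell population engaged by drug
    (monovalently bound plus bridged), in [0, 1] at every reported time."""
    m = trajectory.model
    w_b, w_br, w_tot = _occupancy_weights(m, trajectory.params, receptor, cell)
    x = trajectory.states[: m.n_species]
    tot = w_tot @ x
    occ = (w_b + w_br) @ x
    return np.where(tot > 0, occ / np.maximum(tot, 1e-300), 0.0)


def effective_receptor_occupancy(trajectory: Trajectory, receptor: str, cell: str) -> np.ndarray:
    """Fraction of the receptor pool engaged specifically in intercellular
    bridges; always pointwise below :func:`receptor_occupancy`."""
    m = trajectory.model
    _w_b, w_br, w_tot = _occupancy_weights(m, trajectory.params, receptor, cell)
    x = trajectory.states[: m.n_species]
    tot = w_tot @ x
    return np.where(tot > 0, (w_br @ x) / np.maximum(tot, 1e-300), 0.0)


# ---------------------------------------------------------------------------
# killing and cell-state distribution


def percent_killing(trajectory: Trajectory, control: Trajectory,
                    lineage: str = "tumor") -> np.ndarray:
    """Control-normalised cytotoxicity, 100 * (1 - N(t)/N_control(t)).

    The lineage total counts free, synapsed and killing-resistant cells; the
    control is the same setup at dose 0.
    """
    if control.setup.dose != 0:
        raise ValueError("control trajectory must be at dose 0")
    if (control.setup.duration != trajectory.setup.duration
            or control.setup.initial_counts != trajectory.setup.initial_counts):
        raise ValueError("control setup does not match treated setup")
    m = trajectory.model
    tot = m.lineage_total(f"cells.{lineage}", trajectory.states, trajectory.params)
    ctrl = control.model.lineage_total(f"cells.{lineage}", control.states, control.params)
    return 100.0 * (1.0 - tot / np.maximum(ctrl, 1e-300))


STATE_KEYS = ("free_inactive", "free_active", "in_effective_synapse",
              "in_ineffective_synapse", "resistant", "killed")


def cell_state_distribution(trajectory: Trajectory,
                            classification: Optional[dict[str, bool]] = None
                            ) -> dict[str, dict[str, np.ndarray]]:
    """Stacked state fractions per lineage over time.

    Fractions are of the cumulative lineage pool (initial + synthesised
    cells) and sum to one at every time: free inactive, free active, in
    effective synapse, in ineffective synapse, killing-resistant, and killed
    (removal by killing or degradation).  ``classification`` maps synapse
    species names to effectiveness (see ``synapsim.compare.classify_synapses``);
    unclassified synapses count as ineffective.
    """
    m = trajectory.model
    classification = classification or {}
    x = trajectory.states[: m.n_species]
    out: dict[str, dict[str, np.ndarray]] = {}
    lineages = sorted({c.lineage for c in m.cells})
    for lineage in lineages:
        comp = {k: np.zeros_like(trajectory.t) for k in STATE_KEYS}
        names = {c.name: c for c in m.cells if c.lineage == lineage}
        for name, c in names.items():
            pool = x[m.species_index(pool_name(name))]
            if c.resistant:
                comp["resistant"] = comp["resistant"] + pool
            elif c.activation_state == "active":
                comp["free_active"] = comp["free_active"] + pool
            else:
                comp["free_inactive"] = comp["free_inactive"] + pool
        for p in m.pairings:
            mult = (p.cell_a in names) + (p.cell_b in names)
            if not mult:
                continue
            key = "in_effective_synapse" if classification.get(syn_name(p), False) \
                else "in_ineffective_synapse"
            comp[key] = comp[key] + mult * x[m.species_index(syn_name(p))]
        total0 = m.lineage_total(f"cells.{lineage}", trajectory.states[:, :1],
                                 trajectory.params)[0]
        synth = trajectory.states[m.flux_index(f"cells.{lineage}", "synth")]
        deg = trajectory.states[m.flux_index(f"cells.{lineage}", "deg")]
        denom = np.maximum(total0 + synth, 1e-300)
        comp["killed"] = deg
        out[lineage] = {k: v / denom for k, v in comp.items()}
    return out


# ---------------------------------------------------------------------------
# tidy export


def trajectory_to_frame(trajectory: Trajectory, species: Optional[list[str]] = None):
    """Long-format (time_h, species, value) DataFrame of a trajectory."""
    import pandas as pd

    m = trajectory.model
    names = species if species is not None else [s.name for s in m.species]
    frames = []
    for name in names:
        frames.append(pd.DataFrame({
            "time_h": trajectory.t,
            "species": name,
            "value": trajectory.series(name),
        }))
    return pd.concat(frames, ignore_index=True)
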