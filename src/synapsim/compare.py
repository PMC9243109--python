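"""Bispecific-vs-trispecific dose--response study.

The bispecific comparator molecule is the same drug with its CD28 arm unable
to bind (kon = 0, hence koff = 0); nothing else changes.  Without a second
shared antigen the bispecific cannot bridge T--T, MM--MM or MM--PBMC pairs,
and naive T cells can never be co-stimulated.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .rulegen import BOUND, GeneratedModel, generate_model, rec_name, syn_name
from .schema import ModelDefinition
from .simulate import (
    ExperimentSetup,
    Trajectory,
    cell_state_distribution,
    effective_receptor_occupancy,
    percent_killing,
    receptor_occupancy,
    simulate,
)

#: 12 log-spaced doses covering the MABEL-to-high-dose window of interest
DEFAULT_DOSES = tuple(np.logspace(-5, 1, 12))

#: relative occupancy below which a bound-receptor pool counts as unoccupied
#: when classifying synapse effectiveness
OCCUPANCY_FLOOR = 1e-9


def make_bispecific(definition: ModelDefinition, arm: str = "CD28") -> ModelDefinition:
    """Bispecific variant: the named arm's kon is set to 0 (koff follows as
    KD*kon = 0); the model structure is otherwise untouched.  Idempotent."""
    names = [a.name for a in definition.arms]
    if arm not in names:
        raise ValueError(f"definition has no {arm!r} arm")
    out = copy.deepcopy(definition)
    out.arm(arm).kon = 0.0
    return out.validate()


def classify_synapses(model: GeneratedModel, trajectory: Optional[Trajectory] = None,
                      bispecific: bool = False,
                      t_index: int = -1) -> dict[str, bool]:
    """Effectiveness of every synapse species: True if it contains an MM cell
    and can lead to T-cell activation or killing.

    Rules: active-T--MM synapses are effective; naive/EM-T--MM synapses are
    effective when the T cell is bridged through CD3 and both its CD3 and
    CD28 pools carry nonzero drug occupancy at the assessed time (so a
    trajectory is required to resolve the conditional cases); MM--MM and
    MM--PBMC synapses are ineffective; synapses without an MM cell are
    ineffective by definition.  For the bispecific variant naive-T synapses
    are always ineffective (no co-stimulation exists).
    """
    out: dict[str, bool] = {}
    cv = {c.name: c for c in model.cells}
    act = model.definition.activation
    for p in model.pairings:
        eff = False
        members = ((p.cell_a, p.receptor_a), (p.cell_b, p.receptor_b))
        has_mm = any(cv[m].lineage == "tumor" for m, _ in members)
        if has_mm:
            for mem, bridge_r in members:
                c = cv[mem]
                if not c.lineage.endswith("-T"):
                    continue
                if c.activation_state == "active":
                    eff = True
                elif c.activation_state in ("naive", "effector-memory"):
                    if bispecific and c.activation_state == "naive":
                        continue
                    if bridge_r != act.cd3_receptor:
                        continue
                    if trajectory is None:
                        eff = True  # structural classification only
                        continue
                    x = trajectory.states[:, t_index]
                    syn = x[model.species_index(syn_name(p))]
                    b3 = x[model.species_index(
                        rec_name(act.cd3_receptor, BOUND, syn_name(p), mem))]
                    b28 = x[model.species_index(
                        rec_name(act.cd28_receptor, BOUND, syn_name(p), mem))]
                    bps = trajectory.params[model.param_index("bridges_per_synapse")]
                    b3 += bps * syn  # bridged CD3 is drug-bound
                    if b3 > OCCUPANCY_FLOOR * max(syn, 1.0) and \
                            b28 > OCCUPANCY_FLOOR * max(syn, 1.0):
                        eff = True
        out[syn_name(p)] = eff
    return out


@dataclass
class DoseResponseTable:
    variant: str
    frame: pd.DataFrame  # one row per dose, mean/sd columns per output

    @property
    def doses(self) -> np.ndarray:
        return self.frame["dose_nM"].to_numpy()


def _synapse_totals(model, traj, classification):
    x = traj.states[: model.n_species]
    eff = np.zeros_like(traj.t)
    ineff = np.zeros_like(traj.t)
    for p in model.pairings:
        s = x[model.species_index(syn_name(p))]
        if classification.get(syn_name(p), False):
            eff = eff + s
        else:
            ineff = ineff + s
    return eff, ineff


def free_active_t(traj: Trajectory) -> np.ndarray:
    """Free (unsynapsed) active T cells over time."""
    m = traj.model
    out = np.zeros_like(traj.t)
    for c in m.cells:
        if c.activation_state == "active":
            out = out + traj.series(f"cell.{c.name}")
    return out


def total_active_t(traj: Trajectory) -> np.ndarray:
    """Active T cells over time, free or engaged in synapse."""
    m = traj.model
    cv = {c.name: c for c in m.cells}
    out = free_active_t(traj)
    for p in m.pairings:
        mult = sum(1 for mem in (p.cell_a, p.cell_b)
                   if cv[mem].activation_state == "active")
        if mult:
            out = out + mult * traj.series(syn_name(p))
    return out


def ineffective_tumor_synapses(traj: Trajectory,
                               classification: Optional[dict[str, bool]] = None
                               ) -> np.ndarray:
    """Copy number of tumor-containing ineffective synapses over time."""
    m = traj.model
    if classification is None:
        classification = classify_synapses(m, traj)
    cv = {c.name: c for c in m.cells}
    out = np.zeros_like(traj.t)
    for p in m.pairings:
        has_mm = cv[p.cell_a].lineage == "tumor" or cv[p.cell_b].lineage == "tumor"
        if has_mm and not classification.get(syn_name(p), False):
            out = out + traj.states[m.species_index(syn_name(p))]
    return out


def dose_response_study(definition: ModelDefinition,
                        population: Sequence[np.ndarray] | Sequence[dict] | None,
                        doses: Sequence[float] = DEFAULT_DOSES,
                        duration: float = 72.0,
                        setup: Optional[ExperimentSetup] = None,
                        variant: str = "trispecific",
                        model: Optional[GeneratedModel] = None) -> DoseResponseTable:
    """Population mean +/- SD of killing, receptor occupancy, effective
    occupancy and cell-state distributions across a dose grid.

    ``population`` is a sequence of parameter vectors (or override dicts);
    ``None`` runs the single default parameterisation.
    """
    doses = list(doses)
    if not doses:
        raise ValueError("dose grid is empty")
    if any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    if model is None:
        model = generate_model(definition)
    if population is None:
        population = [model.default_params()]
    base = setup or ExperimentSetup(dose=0.0, duration=duration)
    rows = []
    receptors = [(r.name, cell) for r in definition.receptors
                 for cell in ("MM",) if cell in r.expressed_on]
    bisp = variant.startswith("bi")
    for member_i, member in enumerate(population):
        p = model.params_with(member) if isinstance(member, dict) else np.asarray(member)
        ctrl = simulate(model, p, base.replace(dose=0.0, label="control"))
        for dose in doses:
            traj = simulate(model, p, base.replace(dose=float(dose), label=f"dose={dose}"))
            classification = classify_synapses(model, traj, bispecific=bisp)
            eff, ineff = _synapse_totals(model, traj, classification)
            dist = cell_state_distribution(traj, classification)
            row = {
                "member": member_i,
                "dose_nM": float(dose),
                "pct_killing": float(percent_killing(traj, ctrl)[-1]),
                "free_active_T": float(free_active_t(traj)[-1]),
                "total_active_T": float(total_active_t(traj)[-1]),
                "effective_synapses": float(eff[-1]),
                "ineffective_synapses": float(ineff[-1]),
                "frac_ineffective": float(ineff[-1] / max(eff[-1] + ineff[-1], 1e-300)),
            }
            for rname, cell in receptors:
                row[f"RO.{rname}.{cell}"] = float(
                    receptor_occupancy(traj, rname, cell)[-1])
                row[f"eRO.{rname}.{cell}"] = float(
                    effective_receptor_occupancy(traj, rname, cell)[-1])
            if "tumor" in dist:
                for k, v in dist["tumor"].items():
                    row[f"MM.{k}"] = float(v[-1])
            rows.append(row)
    df = pd.DataFrame(rows)
    agg = df.groupby("dose_nM").agg(["mean", "std"])
    agg.columns = [f"{a}_{b}" for a, b in agg.columns]
    agg = agg.reset_index().sort_values("dose_nM").reset_index(drop=True)
    return DoseResponseTable(variant=variant, frame=agg)


# ---------------------------------------------------------------------------
# curve-shape detectors and bi/tri comparison


def is_plateau(doses: np.ndarray, values: np.ndarray, frac: float = 0.10) -> bool:
    """Final third of the grid within ``frac`` of the grid maximum."""
    values = np.asarray(values, dtype=float)
    vmax = values.max()
    if vmax <= 0:
        return False
    tail = values[len(values) - len(values) // 3:]
    return bool(np.all(tail >= (1 - frac) * vmax))


def is_bell(doses: np.ndarray, values: np.ndarray, frac: float = 0.10) -> bool:
    """Interior maximum exceeding both endpoint values by more than ``frac``."""
    values = np.asarray(values, dtype=float)
    i = int(np.argmax(values))
    if i == 0 or i == len(values) - 1:
        return False
    vmax = values[i]
    if vmax <= 0:
        return False
    return bool(vmax > (1 + frac) * values[0] and vmax > (1 + frac) * values[-1])


@dataclass
class ComparisonSummary:
    fold_advantage: pd.DataFrame  # dose_nM, tri, bi, ratio
    max_advantage: float
    max_advantage_dose: float
    tri_killing_plateau: bool
    bi_killing_bell: bool

    def to_dict(self) -> dict:
        return {
            "max_advantage": self.max_advantage,
            "max_advantage_dose_nM": self.max_advantage_dose,
            "tri_killing_plateau": self.tri_killing_plateau,
            "bi_killing_bell": self.bi_killing_bell,
        }


def compare_bi_tri(tri: DoseResponseTable, bi: DoseResponseTable) -> ComparisonSummary:
    """Per-dose trispecific:bispecific mean-killing ratio and shape calls."""
    if not np.allclose(tri.doses, bi.doses):
        raise ValueError("dose grids do not match")
    t = tri.frame["pct_killing_mean"].to_numpy()
    b = bi.frame["pct_killing_mean"].to_numpy()
    ratio = t / np.maximum(b, 1e-12)
    df = pd.DataFrame({"dose_nM": tri.doses, "tri_killing": t, "bi_killing": b,
                       "ratio": ratio})
    i = int(np.argmax(ratio))
    return ComparisonSummary(
        fold_advantage=df,
        max_advantage=float(ratio[i]),
        max_advantage_dose=float(tri.doses[i]),
        tri_killing_plateau=is_plateau(tri.doses, t),
        bi_killing_bell=is_bell(bi.doses, b),
    )
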