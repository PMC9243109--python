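"""Synthetic in vitro datasets emulating the five calibration/qualification
experiments, generated by simulating a model variant at known "true"
parameters and adding measurement noise.

Experiments
-----------
``activation``
    PBMC incubation; % activated T cells after 24 h across doses.
``cytotoxicity``
    Pre-activated CD8 T cells with a tumor line (CD38-high at 1.29e5 or
    CD38-low at 2.5e3 receptors/cell); % killing after 24 h across doses.
``cytokine-range``
    PBMC incubation; per-cytokine (min, max) bands across simulated donor
    replicates after 24 h, emulating a wide-range MIMIC-style readout.
``proliferation``
    1e5 sorted T cells, 6-day total-T time course at a high dose.
``qualification-cytotoxicity``
    2e5 PBMCs + 2e4 tumor cells (10:1 E:T), % killing after 24 h.

Each dataset records its generating truth and seed so closed-loop
parameter-recovery experiments can score themselves automatically.
Point observations get multiplicative lognormal noise (relative sd in
log-space); range data are min/max envelopes over noisy replicates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import presets
from .rulegen import GeneratedModel, generate_model
from .simulate import ExperimentSetup, percent_killing, simulate
from .compare import total_active_t

EXPERIMENT_KINDS = ("activation", "cytotoxicity", "cytokine-range",
                    "proliferation", "qualification-cytotoxicity")

DEFAULT_DOSE_GRID = tuple(np.logspace(-4, 0.5, 7))


@dataclass
class GeneratorConfig:
    kind: str
    doses: Sequence[float] = DEFAULT_DOSE_GRID
    true_params: dict[str, float] = field(default_factory=dict)
    replicates: int = 1
    noise_rel_sd: float = 0.05
    band_rel_spread: float = 0.30
    band_replicates: int = 10
    seed: int = 0
    cd38_per_cell: float = presets.CD38_HIGH
    duration: float = 24.0
    #: observation times within the incubation (None = endpoint only);
    #: kinetic readouts separate rate parameters that endpoint data confound
    times: Optional[Sequence[float]] = None
    proliferation_dose: float = 1.0  # nM
    t_subsets: tuple[str, ...] = ("CD4-T", "CD8-T")
    # solver tolerances used for this experiment's simulations; the default
    # trades a little tail accuracy for a ~2x faster calibration loop
    rtol: float = 1e-6
    atol: float = 1e-2

    def __post_init__(self):
        if self.kind not in EXPERIMENT_KINDS:
            raise ValueError(f"unsupported experiment kind {self.kind!r}")
        if self.noise_rel_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")


@dataclass
class CalibrationDataset:
    kind: str
    frame: pd.DataFrame  # experiment, dose_nM, time_h, observable, value[, value_min/max], units
    config: Optional[GeneratorConfig] = None
    truth: Optional[dict[str, float]] = None
    seed: Optional[int] = None

    @property
    def is_range(self) -> bool:
        return "value_min" in self.frame.columns

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)
        if self.config is not None:
            sidecar = Path(path).with_suffix(".manifest.json")
            sidecar.write_text(json.dumps(truth_manifest(self), indent=2))

    @staticmethod
    def from_csv(path) -> "CalibrationDataset":
        frame = pd.read_csv(path)
        kind = frame["experiment"].iloc[0]
        ds = CalibrationDataset(kind=kind, frame=frame)
        sidecar = Path(path).with_suffix(".manifest.json")
        if sidecar.exists():
            man = json.loads(sidecar.read_text())
            ds.truth = man["truth"]
            ds.seed = man["seed"]
            ds.config = GeneratorConfig(**man["config"])
        return ds


# ---------------------------------------------------------------------------
# model variants and noise-free predictions


def experiment_model(config: GeneratorConfig) -> GeneratedModel:
    kind = config.kind
    if kind in ("activation", "cytokine-range"):
        defn = presets.activation_stage_definition(t_subsets=config.t_subsets)
    elif kind == "cytotoxicity":
        defn = presets.cytotoxicity_stage_definition(cd38_per_cell=config.cd38_per_cell)
    elif kind == "proliferation":
        defn = presets.proliferation_definition()
    else:
        defn = presets.qualification_definition(cd38_per_cell=config.cd38_per_cell)
    return generate_model(defn)


def predict(model: GeneratedModel, params, config: GeneratorConfig) -> pd.DataFrame:
    """Noise-free observations for an experiment at given parameters.

    Returns tidy rows (experiment, dose_nM, time_h, observable, value, units).
    """
    kind = config.kind
    rows = []
    if kind == "proliferation":
        setup = ExperimentSetup(dose=config.proliferation_dose, duration=144.0)
        traj = simulate(model, params, setup, rtol=config.rtol, atol=config.atol)
        tot = sum(
            model.lineage_total(f"cells.{lin}", traj.states, traj.params)
            for lin in ("CD4-T", "CD8-T")
            if any(c.lineage == lin for c in model.cells)
        )
        for day in range(0, 7):
            i = int(np.argmin(np.abs(traj.t - 24.0 * day)))
            rows.append({"experiment": kind, "dose_nM": config.proliferation_dose,
                         "time_h": 24.0 * day, "observable": "total_T",
                         "value": float(tot[i]), "units": "cells"})
        return pd.DataFrame(rows)

    base = ExperimentSetup(dose=0.0, duration=config.duration)
    needs_control = kind in ("cytotoxicity", "qualification-cytotoxicity")
    ctrl = (simulate(model, params, base, rtol=config.rtol, atol=config.atol)
            if needs_control else None)
    times = list(config.times) if config.times else [config.duration]
    for dose in config.doses:
        traj = simulate(model, params, base.replace(dose=float(dose)),
                        rtol=config.rtol, atol=config.atol)
        idx = [int(np.argmin(np.abs(traj.t - tt))) for tt in times]
        if kind == "activation":
            t_lineages = [lin for lin in ("CD4-T", "CD8-T")
                          if any(c.lineage == lin for c in model.cells)]
            tot_t = sum(model.lineage_total(f"cells.{lin}", traj.states, traj.params)
                        for lin in t_lineages)
            act = total_active_t(traj)
            for i in idx:
                rows.append({"experiment": kind, "dose_nM": float(dose),
                             "time_h": float(traj.t[i]),
                             "observable": "pct_activated_T",
                             "value": 100.0 * act[i] / max(tot_t[i], 1e-300),
                             "units": "%"})
        elif needs_control:
            pk = percent_killing(traj, ctrl)
            for i in idx:
                rows.append({"experiment": kind, "dose_nM": float(dose),
                             "time_h": float(traj.t[i]), "observable": "pct_killing",
                             "value": float(pk[i]), "units": "%"})
        else:  # cytokine-range
            for cy in model.definition.cytokines:
                series = traj.series(f"cyt.{cy.name}")
                for i in idx:
                    rows.append({"experiment": kind, "dose_nM": float(dose),
                                 "time_h": float(traj.t[i]),
                                 "observable": f"cytokine_{cy.name}",
                                 "value": float(series[i]),
                                 "units": "molecules"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset generation


def generate_dataset(config: GeneratorConfig,
                     model: Optional[GeneratedModel] = None) -> CalibrationDataset:
    """Simulate the experiment at the true parameters and sample noisy
    observations (or min/max bands for range data)."""
    if model is None:
        model = experiment_model(config)
    params = model.params_with(config.true_params)
    clean = predict(model, params, config)
    rng = np.random.default_rng(config.seed)
    truth = {p.name: float(params[i]) for i, p in enumerate(model.parameters)}

    if config.kind == "cytokine-range":
        reps = []
        for _ in range(config.band_replicates):
            noisy = clean["value"].to_numpy() * rng.lognormal(
                mean=0.0, sigma=config.band_rel_spread, size=len(clean))
            reps.append(noisy)
        reps = np.array(reps)
        frame = clean.drop(columns=["value"]).copy()
        frame["value_min"] = np.minimum(reps.min(axis=0), clean["value"].to_numpy())
        frame["value_max"] = np.maximum(reps.max(axis=0), clean["value"].to_numpy())
    else:
        parts = []
        for rep in range(config.replicates):
            part = clean.copy()
            part["replicate"] = rep
            if config.noise_rel_sd > 0:
                part["value"] = part["value"].to_numpy() * rng.lognormal(
                    mean=0.0, sigma=config.noise_rel_sd, size=len(part))
            parts.append(part)
        frame = pd.concat(parts, ignore_index=True)
    return CalibrationDataset(kind=config.kind, frame=frame, config=config,
                              truth=truth, seed=config.seed)


class AbsentTruthError(KeyError):
    pass


def truth_manifest(dataset: CalibrationDataset) -> dict:
    """Exact generating truth (parameters, seed, config) of a dataset.

    Raises :class:`AbsentTruthError` for externally supplied data.
    """
    if dataset.truth is None or dataset.config is None:
        raise AbsentTruthError("dataset was not produced by this generator")
    cfg = asdict(dataset.config)
    cfg["doses"] = [float(d) for d in cfg["doses"]]
    cfg["t_subsets"] = tuple(cfg["t_subsets"])
    body = {"truth": dataset.truth, "seed": dataset.seed, "config": cfg}
    digest = hashlib.sha256(
        json.dumps(body, sort_keys=True, default=list).encode()).hexdigest()
    return {**body, "sha256": digest}


def recovery_errors(dataset: CalibrationDataset,
                    fitted: dict[str, float]) -> dict[str, float]:
    """Relative error of each fitted parameter against the dataset's truth."""
    man = truth_manifest(dataset)
    truth = man["truth"]
    out = {}
    for name, value in fitted.items():
        true = truth.get(name)
        if true is None and name == "collision_factor":
            pair_values = [v for k, v in truth.items() if k.startswith("collision.")]
            true = pair_values[0] if pair_values else None
        if true is None or true == 0:
            continue
        out[name] = abs(value - true) / abs(true)
    return out
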