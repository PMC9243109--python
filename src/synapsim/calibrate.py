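"""Staged calibration and range-fitted virtual populations.

Calibration proceeds in stages, each against the dataset that isolates the
relevant mechanism: synapse/activation parameters against PBMC activation
data (no tumor present, so no confounding killing), killing and resistance
against pre-activated-CD8 cytotoxicity data for a CD38-high and a CD38-low
line (activation parameters frozen), and cytokine production against
range-valued cytokine data, fitted to the *range* rather than the median.
The optimiser is a seeded population-based global stochastic search
(differential evolution); the final optimiser population filtered by
band coverage provides the virtual-population members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .rulegen import GeneratedModel
from .synth import CalibrationDataset, experiment_model, predict

STAGES = ("activation", "cytotoxicity", "cytokine-range")

#: default search spaces (linear scale; optimisation runs in log10 space)
DEFAULT_BOUNDS = {
    "activation": {
        "kon.CD3": (5e-2, 1.0),
        "k_act.EM": (5e-2, 1.0),
        "k_act.naive": (5e-2, 1.5),
        "collision_factor": (5e-4, 8e-3),
    },
    "cytotoxicity": {
        "k_kill.CD8-T.tumor": (4e-2, 4.0),
        "k_res": (5e-3, 0.5),
    },
}

#: fraction of points that must fall inside the bands for a candidate to be
#: accepted into the range-fit population
BAND_COVERAGE = 0.90


class UnidentifiableStageWarning(UserWarning):
    pass


@dataclass
class FitResult:
    stage: str
    params: dict[str, float]  # fitted values, linear scale
    loss: float
    n_evaluations: int
    bounds: dict[str, tuple[float, float]]
    population: Optional[list[dict[str, float]]] = None  # accepted members
    population_energies: Optional[np.ndarray] = None


@dataclass
class VirtualPopulation:
    members: list[dict[str, float]]  # parameter overrides per member
    bounds: dict[str, tuple[float, float]]
    accepted: int
    resampled: bool = False

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# meta-parameter mapping


def expand_meta(model: GeneratedModel, overrides: dict[str, float]) -> dict[str, float]:
    """Map calibration names onto model parameters.  ``collision_factor``
    fans out to every per-pair collision parameter."""
    out: dict[str, float] = {}
    pnames = {p.name for p in model.parameters}
    for name, value in overrides.items():
        if name == "collision_factor":
            for pn in pnames:
                if pn.startswith("collision."):
                    out[pn] = value
        elif name in pnames:
            out[name] = value
        # silently skip parameters absent from this stage's reduced model
    return out


# ---------------------------------------------------------------------------
# loss


def loss_value(predictions: pd.DataFrame, dataset: CalibrationDataset,
               mode: str) -> float:
    """Sum of squared normalised residuals (``point``) or squared distances
    to the nearest band edge, zero inside the band (``range``).

    The normalisation scale is the per-observable median of the observations
    (so % observables and molecule-scale cytokines mix on equal footing).
    """
    keys = ["experiment", "dose_nM", "time_h", "observable"]
    obs = dataset.frame
    if mode == "point":
        o = obs.groupby(keys, as_index=False)["value"].mean()
        merged = o.merge(predictions, on=keys, suffixes=("_obs", "_pred"))
        scale = merged.groupby("observable")["value_obs"].transform(
            lambda s: max(abs(s.median()), 1e-12))
        r = (merged["value_pred"] - merged["value_obs"]) / scale
        return float(np.sum(r.to_numpy() ** 2))
    if mode == "range":
        merged = obs.merge(predictions, on=keys)
        mid = (merged["value_min"] + merged["value_max"]) / 2
        scale = mid.groupby(merged["observable"]).transform(
            lambda s: max(abs(s.median()), 1e-12))
        below = np.maximum(merged["value_min"] - merged["value"], 0.0)
        above = np.maximum(merged["value"] - merged["value_max"], 0.0)
        r = (below + above) / scale
        return float(np.sum(r.to_numpy() ** 2))
    raise ValueError(f"unknown loss mode {mode!r}")


def loss(params: dict[str, float], dataset: CalibrationDataset, mode: str,
         model: Optional[GeneratedModel] = None) -> float:
    """Loss of a parameter override set against one dataset."""
    if model is None:
        if dataset.config is None:
            raise ValueError("dataset carries no experiment config; pass model=")
        model = experiment_model(dataset.config)
    p = model.params_with(expand_meta(model, params))
    pred = predict(model, p, dataset.config)
    return loss_value(pred, dataset, mode)


def band_coverage(predictions: pd.DataFrame, dataset: CalibrationDataset) -> float:
    """Fraction of observation points whose prediction lies inside the band."""
    keys = ["experiment", "dose_nM", "time_h", "observable"]
    merged = dataset.frame.merge(predictions, on=keys)
    inside = ((merged["value"] >= merged["value_min"])
              & (merged["value"] <= merged["value_max"]))
    return float(inside.mean())


# ---------------------------------------------------------------------------
# staged fitting


def _as_list(x) -> list:
    return list(x) if isinstance(x, (list, tuple)) else [x]


def fit_stage(stage: str,
              datasets: Union[CalibrationDataset, Sequence[CalibrationDataset]],
              frozen_params: Optional[dict[str, float]] = None,
              bounds: Optional[dict[str, tuple[float, float]]] = None,
              seed: int = 0,
              popsize: int = 12,
              maxiter: int = 25,
              tol: float = 1e-3,
              polish: bool = True) -> FitResult:
    """Fit one calibration stage with earlier-stage parameters frozen.

    ``activation`` and ``cytotoxicity`` are point fits; ``cytokine-range``
    fits the observation bands and additionally returns the accepted
    optimiser-population members (band coverage >= 90% of points).
    A flat final population triggers an :class:`UnidentifiableStageWarning`.
    Deterministic for a fixed seed.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    datasets = _as_list(datasets)
    frozen = dict(frozen_params or {})
    mode = "range" if stage == "cytokine-range" else "point"
    if bounds is None:
        if stage == "cytokine-range":
            bounds = _default_cytokine_bounds(datasets[0])
        else:
            bounds = dict(DEFAULT_BOUNDS[stage])
    names = list(bounds)
    models = [experiment_model(ds.config) for ds in datasets]
    log_bounds = [(np.log10(lo), np.log10(hi)) for lo, hi in bounds.values()]

    nev = 0

    def objective(theta_log: np.ndarray) -> float:
        nonlocal nev
        nev += 1
        theta = {n: 10.0 ** v for n, v in zip(names, theta_log)}
        total = 0.0
        for model, ds in zip(models, datasets):
            over = expand_meta(model, {**frozen, **theta})
            pred = predict(model, model.params_with(over), ds.config)
            total += loss_value(pred, ds, mode)
        return total

    result = differential_evolution(
        objective, log_bounds, seed=seed, popsize=popsize, maxiter=maxiter,
        tol=tol, polish=polish, init="sobol", updating="deferred")
    fitted = {n: float(10.0 ** v) for n, v in zip(names, result.x)}
    energies = np.asarray(result.population_energies)
    if np.ptp(energies) < 1e-12:
        warnings.warn(
            f"stage {stage!r}: flat loss over the final optimiser population; "
            "fitted parameters may be unidentifiable", UnidentifiableStageWarning)

    population = None
    if stage == "cytokine-range":
        population = []
        for vec in result.population:
            theta = {n: float(10.0 ** v) for n, v in zip(names, vec)}
            cov = []
            for model, ds in zip(models, datasets):
                over = expand_meta(model, {**frozen, **theta})
                pred = predict(model, model.params_with(over), ds.config)
                cov.append(band_coverage(pred, ds))
            if min(cov) >= BAND_COVERAGE:
                population.append(theta)
    return FitResult(stage=stage, params=fitted, loss=float(result.fun),
                     n_evaluations=nev, bounds=bounds, population=population,
                     population_energies=energies)


def _default_cytokine_bounds(dataset: CalibrationDataset) -> dict:
    model = experiment_model(dataset.config)
    out = {}
    for p in model.parameters:
        if p.name.startswith("k_cyt."):
            out[p.name] = (p.value / 10.0, p.value * 10.0)
    if not out:
        raise ValueError("stage model has no cytokine production parameters")
    return out


def fit_extremes(dataset: CalibrationDataset,
                 frozen_params: Optional[dict[str, float]] = None,
                 bounds: Optional[dict[str, tuple[float, float]]] = None,
                 seed: int = 0, popsize: int = 12, maxiter: int = 25
                 ) -> dict[str, FitResult]:
    """Traditional distance fits to the band minima and maxima.

    Used to verify that the range-fitted population's prediction envelope
    lies between the two extreme point-fits.
    """
    if not dataset.is_range:
        raise ValueError("fit_extremes requires a range dataset")
    b = bounds or _default_cytokine_bounds(dataset)
    names = list(b)
    log_bounds = [(np.log10(lo), np.log10(hi)) for lo, hi in b.values()]
    model = experiment_model(dataset.config)
    out = {}
    for which, col in (("min", "value_min"), ("max", "value_max")):
        frame = dataset.frame.rename(columns={col: "value"}).drop(
            columns=[c for c in ("value_min", "value_max") if c != col])
        point_ds = CalibrationDataset(kind=dataset.kind, frame=frame,
                                      config=dataset.config,
                                      truth=dataset.truth, seed=dataset.seed)

        def pobj(theta_log):
            theta = {n: 10.0 ** v for n, v in zip(names, theta_log)}
            over = expand_meta(model, {**(frozen_params or {}), **theta})
            pred = predict(model, model.params_with(over), point_ds.config)
            return loss_value(pred, point_ds, "point")

        result = differential_evolution(
            pobj, log_bounds, seed=seed, popsize=popsize,
            maxiter=maxiter, tol=1e-3, polish=False, init="sobol",
            updating="deferred")
        out[which] = FitResult(
            stage=f"extreme-{which}",
            params={n: float(10.0 ** v) for n, v in zip(names, result.x)},
            loss=float(result.fun), n_evaluations=int(result.nfev),
            bounds=dict(b))
    return out


# ---------------------------------------------------------------------------
# virtual population


def build_virtual_population(stage_results: dict[str, FitResult],
                             total_t_cells: float,
                             n: int,
                             seed: int = 0,
                             composition: Optional[dict[str, float]] = None
                             ) -> VirtualPopulation:
    """Assemble n parameter vectors from the staged fits.

    Point-fitted activation and cytotoxicity parameters are shared; the
    cytokine-range stage contributes its accepted population (resampled with
    replacement, flagged, if fewer than n members were accepted).  Initial
    T-subset counts are drawn from the configured peripheral-blood
    composition and rescaled so subsets preserve their ratios at the
    requested total T-cell number.
    """
    from . import presets

    rng = np.random.default_rng(seed)
    base: dict[str, float] = {}
    for key in ("activation", "cytotoxicity"):
        if key in stage_results:
            base.update(stage_results[key].params)
    accepted: list[dict[str, float]] = []
    bounds: dict[str, tuple[float, float]] = {}
    for res in stage_results.values():
        bounds.update(res.bounds)
    if "cytokine-range" in stage_results:
        accepted = stage_results["cytokine-range"].population or []
    comp = composition or {k: v for k, v in presets.BLOOD_PER_ML.items()
                           if not k.startswith(("MM", "PBMC"))}
    t_total_ref = sum(comp.values())
    counts = {f"N0.{k}": total_t_cells * v / t_total_ref for k, v in comp.items()}

    resampled = False
    members = []
    if accepted:
        idx = np.arange(len(accepted))
        if len(accepted) < n:
            resampled = True
            idx = rng.choice(len(accepted), size=n, replace=True)
        else:
            idx = rng.choice(len(accepted), size=n, replace=False)
        for i in idx:
            members.append({**base, **accepted[int(i)], **counts})
    else:
        members = [{**base, **counts} for _ in range(n)]
    return VirtualPopulation(members=members, bounds=bounds,
                             accepted=len(accepted), resampled=resampled)
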