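"""Latin-hypercube sampling and PRCC global sensitivity analysis.

Parameters are varied a fixed fraction (default +/-10%) around their
baseline values with one stratified sample per quantile bin; each model
output of interest is reduced to the area under its time course (AUC), and
partial rank correlation coefficients are computed per parameter x output
with t-statistic p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .rulegen import GeneratedModel
from .simulate import ExperimentSetup, Trajectory, percent_killing, simulate
from . import compare as _compare


def lhs_sample(baseline: dict[str, float], spread: float, n: int,
               seed: int) -> pd.DataFrame:
    """Latin-hypercube sample, uniform on [base*(1-spread), base*(1+spread)].

    Every parameter's marginal places exactly one sample in each of the n
    equal-probability strata.  Raises on non-positive baselines, which have
    no meaningful multiplicative neighbourhood.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < spread < 1:
        raise ValueError("spread must be in (0, 1)")
    names = list(baseline)
    base = np.array([baseline[k] for k in names], dtype=float)
    if np.any(base <= 0):
        bad = [k for k, v in baseline.items() if v <= 0]
        raise ValueError(f"non-positive baselines cannot be sampled multiplicatively: {bad}")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    u = sampler.random(n)
    lo = base * (1 - spread)
    hi = base * (1 + spread)
    return pd.DataFrame(qmc.scale(u, lo, hi), columns=names)


# ---------------------------------------------------------------------------
# named output series and their AUCs

OUTPUT_NAMES = ("tumor_killing", "total_active_T", "free_active_T",
                "ineffective_T_MM_synapses")


def output_series(traj: Trajectory, name: str,
                  control: Optional[Trajectory] = None) -> np.ndarray:
    if name == "tumor_killing":
        if control is None:
            raise ValueError("tumor_killing requires the dose-0 control trajectory")
        return percent_killing(traj, control)
    if name == "total_active_T":
        return _compare.total_active_t(traj)
    if name == "free_active_T":
        return _compare.free_active_t(traj)
    if name == "ineffective_T_MM_synapses":
        return _compare.ineffective_tumor_synapses(traj)
    raise KeyError(f"unknown output {name!r}")


def auc_outputs(traj: Trajectory, outputs: Sequence[str],
                control: Optional[Trajectory] = None) -> dict[str, float]:
    """Trapezoidal AUC of each named output over the reporting grid."""
    return {
        name: float(np.trapezoid(output_series(traj, name, control), traj.t))
        for name in outputs
    }


# ---------------------------------------------------------------------------
# PRCC


@dataclass
class PRCCResult:
    coefficients: pd.DataFrame  # parameters x outputs
    p_values: pd.DataFrame
    n: int
    dose: Optional[float] = None
    degenerate_outputs: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        rows = []
        for param in self.coefficients.index:
            for out in self.coefficients.columns:
                rows.append({
                    "parameter": param, "output": out, "dose_nM": self.dose,
                    "prcc": self.coefficients.loc[param, out],
                    "p_value": self.p_values.loc[param, out],
                })
        return pd.DataFrame(rows)


def prcc(samples: pd.DataFrame, outputs: pd.DataFrame,
         dose: Optional[float] = None) -> PRCCResult:
    """Partial rank correlation of each parameter against each output.

    All columns are rank-transformed; the coefficient for parameter j is the
    correlation between the residuals of rank(x_j) and rank(y) after linear
    regression on the ranks of all other parameters.  Computed via the
    precision matrix of the pooled rank-correlation matrix.  p-values use the
    t statistic with n - 2 - (p - 1) degrees of freedom.  Constant outputs
    are flagged degenerate and reported as coefficient 0, p 1.
    """
    X = np.asarray(samples, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 samples (n={n}, p={p})")
    Xr = np.apply_along_axis(stats.rankdata, 0, X)
    coefs = pd.DataFrame(index=samples.columns, columns=outputs.columns, dtype=float)
    pvals = pd.DataFrame(index=samples.columns, columns=outputs.columns, dtype=float)
    degenerate = []
    dof = n - 2 - (p - 1)
    for out in outputs.columns:
        y = np.asarray(outputs[out], dtype=float)
        if np.ptp(y) == 0 or not np.all(np.isfinite(y)):
            degenerate.append(out)
            coefs[out] = 0.0
            pvals[out] = 1.0
            continue
        yr = stats.rankdata(y)
        M = np.column_stack([Xr, yr])
        C = np.corrcoef(M, rowvar=False)
        Cinv = np.linalg.pinv(C)
        for j, param in enumerate(samples.columns):
            denom = Cinv[j, j] * Cinv[p, p]
            r = -Cinv[j, p] / np.sqrt(denom) if denom > 0 else 0.0
            r = float(np.clip(r, -1.0, 1.0))
            coefs.loc[param, out] = r
            if abs(r) >= 1.0:
                pvals.loc[param, out] = 0.0
            else:
                t = r * np.sqrt(dof / (1 - r * r))
                pvals.loc[param, out] = float(2 * stats.t.sf(abs(t), dof))
    return PRCCResult(coefficients=coefs, p_values=pvals, n=n, dose=dose,
                      degenerate_outputs=degenerate)


def filter_significant(result: PRCCResult, alpha: float = 0.01,
                       magnitude: float = 0.80) -> dict[str, list[str]]:
    """Retained parameters per output: p < alpha; the heatmap subset
    additionally requires |PRCC| > magnitude on at least one output
    (returned under the pseudo-output key ``"__heatmap__"``)."""
    out: dict[str, list[str]] = {}
    strong = set()
    for col in result.coefficients.columns:
        kept = [
            param for param in result.coefficients.index
            if result.p_values.loc[param, col] < alpha
        ]
        out[col] = kept
        for param in kept:
            if abs(result.coefficients.loc[param, col]) > magnitude:
                strong.add(param)
    out["__heatmap__"] = sorted(strong)
    return out


# ---------------------------------------------------------------------------
# end-to-end study on a generated model


def sample_parameters(model: GeneratedModel, spread: float, n: int, seed: int,
                      exclude: Sequence[str] = ("dose",)) -> tuple[pd.DataFrame, list[str]]:
    """LHS over every strictly positive model parameter (zero-baseline
    parameters, e.g. a disabled arm's kon, are reported fixed and excluded)."""
    baseline = {}
    fixed = []
    for prm in model.parameters:
        if prm.name in exclude or prm.value <= 0:
            fixed.append(prm.name)
        else:
            baseline[prm.name] = prm.value
    return lhs_sample(baseline, spread, n, seed), fixed


def prcc_study(model: GeneratedModel, doses: Sequence[float],
               duration: float = 24.0, spread: float = 0.10, n: int = 200,
               seed: int = 0,
               outputs: Sequence[str] = OUTPUT_NAMES,
               setup: Optional[ExperimentSetup] = None,
               rtol: float = 1e-6, atol: float = 1e-2) -> dict[float, PRCCResult]:
    """Fig-3-style workflow: one LHS population, simulated at each dose, AUC
    outputs, PRCC per dose.  Returns one result (heatmap-ready via
    ``.frame()``) per dose."""
    samples, _fixed = sample_parameters(model, spread, n, seed)
    base = setup or ExperimentSetup(dose=0.0, duration=duration)
    results = {}
    for dose in doses:
        rows = []
        for i in range(len(samples)):
            overrides = samples.iloc[i].to_dict()
            p = model.params_with(overrides)
            ctrl = simulate(model, p, base.replace(dose=0.0), rtol=rtol, atol=atol)
            traj = simulate(model, p, base.replace(dose=float(dose)), rtol=rtol, atol=atol)
            rows.append(auc_outputs(traj, outputs, control=ctrl))
        results[float(dose)] = prcc(samples, pd.DataFrame(rows), dose=float(dose))
    return results
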