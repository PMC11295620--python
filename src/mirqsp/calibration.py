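"""Pooled nonlinear least-squares calibration of model parameters.

Unknown parameters are estimated by fitting the model simultaneously
to all arms of a preclinical tumor-growth dataset: each arm is
simulated under its exact dosing protocol, residuals are pooled across
arms (log-volume scale by default, which weights the fast-growing and
well-controlled arms comparably), and a seeded multi-start
Levenberg-Marquardt / trust-region search guards against local minima.
Goodness of fit is summarized by the Pearson correlation between all
pooled observed and predicted volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .model import SimulationError, equilibrium_state, simulate
from .parameters import ModelParameters
from .synthetic import PreclinicalDataset

__all__ = ["FitResult", "fit_parameters", "goodness_of_fit"]


@dataclass
class FitResult:
    """Outcome of a pooled multi-arm calibration."""

    estimates: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    rss: float
    predictions: pd.DataFrame          # arm, time_day, observed, predicted (mm^3)
    pearson_r: float
    pearson_p: float
    start_diagnostics: pd.DataFrame = field(default=None)

    def within_bounds(self) -> bool:
        return all(
            self.bounds[k][0] <= v <= self.bounds[k][1]
            for k, v in self.estimates.items()
        )


def goodness_of_fit(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation and two-sided p-value."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need aligned arrays of length >= 3")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = pearsonr(obs, pred)
    return float(r), float(p)


def _predict_arms(
    params: ModelParameters,
    dataset: PreclinicalDataset,
    arms: list[str],
    rtol: float,
) -> pd.DataFrame:
    rows = []
    for label in arms:
        proto = dataset.protocols[label]
        days = np.asarray(dataset.arms[label]["time_day"], float)
        y0 = equilibrium_state(params, proto["v0"])
        tr = simulate(params, proto["regimen"], (days[0], days[-1]),
                      initial=y0, rtol=rtol, t_eval_step=2.0)
        pred = 1000.0 * np.interp(days, tr.t, tr.volume)
        obs = np.asarray(dataset.arms[label]["mean_volume_mm3"], float)
        rows.append(pd.DataFrame({
            "arm": label, "time_day": days,
            "observed": obs, "predicted": pred,
        }))
    return pd.concat(rows, ignore_index=True)


def fit_parameters(
    dataset: PreclinicalDataset,
    free_params: list[str],
    base: ModelParameters | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    init: dict[str, float] | None = None,
    arms: list[str] | None = None,
    n_starts: int = 10,
    seed: int = 0,
    log_residuals: bool = True,
    rtol: float = 1e-6,
) -> FitResult:
    """Estimate ``free_params`` by pooled least squares on arm means.

    Bounds default to two orders of magnitude around the initial
    values; starts beyond the first are log-uniform draws within the
    bounds (seeded).  Raises if every start fails, with per-start
    diagnostics in the message.
    """
    unknown = set(free_params) - set(ModelParameters.names())
    if unknown:
        raise KeyError(f"unknown free parameters: {sorted(unknown)}")
    if base is None:
        base = ModelParameters.from_dict(dict(dataset.truth["params"]))
    arms = arms or list(dataset.arms)
    for label in arms:
        if label not in dataset.protocols:
            raise KeyError(f"arm {label!r} has no declared protocol")
    init = init or {k: getattr(base, k) for k in free_params}
    x0 = np.array([init[k] for k in free_params])
    if bounds is None:
        bounds = {k: (init[k] * 1e-2, init[k] * 1e2) for k in free_params}
    lb = np.array([bounds[k][0] for k in free_params])
    ub = np.array([bounds[k][1] for k in free_params])

    obs_all = []
    for label in arms:
        obs_all.append(np.asarray(dataset.arms[label]["mean_volume_mm3"], float))
    obs_cat = np.concatenate(obs_all)
    log_obs = np.log(np.maximum(obs_cat, 1e-9))

    def residuals(x: np.ndarray) -> np.ndarray:
        p = base.replace(**{k: float(v) for k, v in zip(free_params, x)})
        pred = _predict_arms(p, dataset, arms, rtol)["predicted"].to_numpy()
        if log_residuals:
            return np.log(np.maximum(pred, 1e-9)) - log_obs
        return pred - obs_cat

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_starts - 1):
        starts.append(np.exp(rng.uniform(np.log(lb), np.log(ub))))

    best = None
    diags = []
    for i, s in enumerate(starts):
        try:
            init_cost = float(np.sum(residuals(s) ** 2))
            sol = least_squares(residuals, s, bounds=(lb, ub),
                                x_scale=np.abs(x0), ftol=1e-10, xtol=1e-10)
            diags.append({"start": i, "cost": 2 * sol.cost,
                          "init_cost": init_cost, "status": sol.status})
            if best is None or sol.cost < best.cost:
                best = sol
        except (SimulationError, ValueError) as exc:
            diags.append({"start": i, "cost": np.inf, "init_cost": np.nan,
                          "status": f"failed: {exc}"})
    diag_df = pd.DataFrame(diags)
    if best is None:
        raise RuntimeError(f"all {n_starts} calibration starts failed:\n{diag_df}")

    estimates = {k: float(v) for k, v in zip(free_params, best.x)}
    fitted = base.replace(**estimates)
    predictions = _predict_arms(fitted, dataset, arms, rtol)
    r, p = goodness_of_fit(predictions["observed"], predictions["predicted"])
    return FitResult(
        estimates=estimates,
        bounds=bounds,
        rss=float(np.sum((predictions["predicted"] - predictions["observed"]) ** 2)),
        predictions=predictions,
        pearson_r=r,
        pearson_p=p,
        start_diagnostics=diag_df,
    )
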