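"""Local and global sensitivity analysis of treatment response.

LSA perturbs one parameter at a time over +/-50% of baseline and
records the resulting TGI curve.  GSA perturbs all parameters jointly
(Latin-hypercube, +/-50%), regresses TGI on the z-scored parameter
values, and uses the standardized regression coefficients as
sensitivity indices (SI).  Replicated GSA gives an SI distribution per
parameter; one-way ANOVA followed by Tukey's HSD turns the
distributions into ordered significance groups ("which parameters
matter, and which are statistically indistinguishable in impact").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .model import equilibrium_state, simulate
from .parameters import ModelParameters
from .response import tgi as compute_tgi
from .sampling import lhs_unit
from .scaling import Regimen

__all__ = [
    "DEFAULT_GSA_PARAMS",
    "SensitivityResult",
    "make_tgi_evaluator",
    "lsa",
    "gsa",
]

#: the 28 biological / therapeutic parameters screened by GSA
DEFAULT_GSA_PARAMS = [
    "gamma", "A_ML", "k_M", "g0_M_c", "g0_M_t", "delta_M", "k_exo",
    "A_AM_M", "delta_AM", "EC50_AM",
    "k_Cl", "delta_NP", "P_NP", "S0", "Len", "Phi_NP", "D_NP", "k_up",
    "delta_chemo", "EC50_cis", "A_MR",
    "delta_immun", "g_L", "delta_L", "k_ML", "Kd_PDL1", "rho_M8", "K",
]


def make_tgi_evaluator(
    regimen: Regimen,
    start_volume: float = 1.77,
    rx_end_day: float = 189.0,
    rtol: float = 1e-6,
) -> Callable[[ModelParameters], float]:
    """TGI-at-end-of-treatment objective for sensitivity analyses.

    Each call simulates both the treated and the control arm under the
    supplied parameters, so parameter perturbations act on tumor growth
    and drug response alike.
    """

    def evaluate(params: ModelParameters) -> float:
        y0 = equilibrium_state(params, start_volume)
        ctrl = simulate(params, None, (0.0, rx_end_day), initial=y0,
                        rtol=rtol, t_eval_step=3.0)
        trt = simulate(params, regimen, (0.0, rx_end_day), initial=y0,
                       rtol=rtol, t_eval_step=3.0)
        return compute_tgi(float(trt.volume[-1]), float(ctrl.volume[-1]),
                           start_volume)

    return evaluate


def lsa(
    evaluator: Callable[[ModelParameters], float],
    base: ModelParameters,
    param: str,
    perturbations: np.ndarray | None = None,
) -> pd.DataFrame:
    """One-at-a-time sensitivity curve for one parameter.

    Returns (perturbation, value, tgi) over the +/-50% grid; failed
    simulations are recorded as NaN, not fatal.
    """
    if param not in ModelParameters.names():
        raise KeyError(f"unknown parameter {param!r}")
    pert = (np.linspace(-0.5, 0.5, 11) if perturbations is None
            else np.asarray(perturbations, float))
    rows = []
    b = getattr(base, param)
    for f in pert:
        value = b * (1.0 + f)
        try:
            y = float(evaluator(base.replace(**{param: value})))
        except Exception:
            y = np.nan
        rows.append({"perturbation": float(f), "value": value, "tgi": y})
    return pd.DataFrame(rows)


@dataclass
class SensitivityResult:
    """Replicated GSA sensitivity indices with Tukey grouping."""

    si: pd.DataFrame                  # columns = parameters, rows = replicates
    ranking: list[str]                # by |mean SI|, descending
    groups: list[list[str]]           # ordered significance groups
    anova_p: float
    mean_si: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.mean_si is None:
            self.mean_si = self.si.mean(axis=0)


def _single_gsa(
    evaluator, base: ModelParameters, names: list[str],
    n: int, range_frac: float, seed: int,
) -> np.ndarray:
    u = lhs_unit(n, len(names), seed)
    X = np.empty((n, len(names)))
    y = np.empty(n)
    for i in range(n):
        overrides = {}
        for j, name in enumerate(names):
            b = getattr(base, name)
            X[i, j] = b * (1 - range_frac + 2 * range_frac * u[i, j])
            overrides[name] = X[i, j]
        y[i] = evaluator(base.replace(**overrides))
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient GSA design matrix")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef[1:]


def gsa(
    evaluator: Callable[[ModelParameters], float],
    base: ModelParameters,
    names: list[str] | None = None,
    n_samples: int = 500,
    replicates: int = 50,
    range_frac: float = 0.50,
    seed: int = 0,
    alpha: float = 0.05,
) -> SensitivityResult:
    """Replicated regression-coefficient GSA with ANOVA/Tukey ranking.

    Per replicate: an LHS of all ``names`` over +/- ``range_frac``,
    model output evaluated at each sample, and SI taken as the
    coefficients of a multivariate linear regression of the output on
    the z-scored parameter values.  Requires
    ``n_samples >= 10 * len(names)`` for a stable regression.
    """
    names = list(names or DEFAULT_GSA_PARAMS)
    if n_samples < 10 * len(names):
        raise ValueError(
            f"n_samples={n_samples} too small for {len(names)} parameters "
            f"(need >= {10 * len(names)})"
        )
    rows = [
        _single_gsa(evaluator, base, names, n_samples, range_frac,
                    seed + 1009 * r)
        for r in range(replicates)
    ]
    si = pd.DataFrame(rows, columns=names)
    ranking = list(si.mean(axis=0).abs().sort_values(ascending=False).index)
    anova_p = float(stats.f_oneway(*[si[c].to_numpy() for c in names]).pvalue)
    groups = _tukey_groups(si, ranking, alpha) if replicates >= 2 else [ranking]
    return SensitivityResult(si=si, ranking=ranking, groups=groups,
                             anova_p=anova_p)


def _tukey_groups(si: pd.DataFrame, ranking: list[str], alpha: float) -> list[list[str]]:
    """Connected components of 'not significantly different' in rank order."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    long = si.melt(var_name="param", value_name="si")
    res = pairwise_tukeyhsd(long["si"].to_numpy(), long["param"].to_numpy(),
                            alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    not_diff = {
        frozenset((str(r["group1"]), str(r["group2"])))
        for _, r in frame.iterrows()
        if not bool(r["reject"])
    }
    groups: list[list[str]] = []
    for p in ranking:
        placed = False
        for g in groups:
            if any(frozenset((p, q)) in not_diff for q in g):
                g.append(p)
                placed = True
                break
        if not placed:
            groups.append([p])
    return groups
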