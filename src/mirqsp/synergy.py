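"""Chou-Talalay combination-index analysis of drug combinations.

The median-effect equation fa/(1-fa) = (D/Dm)^m linearizes to
log(fa/(1-fa)) = m log D - m log Dm, so each monotherapy's
median-effect dose Dm and shape m come from a straight-line fit of the
log-logit of the affected fraction against log dose.  For a
combination at doses d_i with observed combined effect fa, the
combination index is

    CI = sum_i d_i / Dx_i,   Dx_i = Dm_i * (fa/(1-fa))^(1/m_i),

the sum of each drug's dose relative to the dose at which it would
produce the combination's effect alone (mutually nonexclusive cross
terms excluded).  CI < 1 indicates Loewe synergy; the classification
thresholds are strong synergy < 0.3, synergy < 0.9, additive 0.9-1.1,
antagonism > 1.1.

The affected fraction here is tumor growth inhibition scaled to (0, 1)
(fa = TGI/100, clipped to [0.01, 0.99]), evaluated at end of treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .model import equilibrium_state, simulate
from .parameters import ModelParameters
from .response import tgi as compute_tgi
from .sampling import lhs_log_doses
from .scaling import Regimen, build_regimen

__all__ = [
    "MedianEffectFit",
    "median_effect_fit",
    "combination_index",
    "classify_ci",
    "sample_dose_combinations",
    "average_patient_fa",
    "make_fa_evaluator",
    "run_combination_study",
    "CI_STRONG_SYNERGY",
    "CI_SYNERGY",
    "CI_ANTAGONISM",
]

CI_STRONG_SYNERGY = 0.3
CI_SYNERGY = 0.9
CI_ANTAGONISM = 1.1

FA_CLIP = (0.01, 0.99)


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect parameters of one drug: Dm (mg/kg) and shape m."""

    Dm: float
    m: float
    drug: str = ""
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.Dm <= 0 or self.m <= 0:
            raise ValueError("Dm and m must be positive")

    def fa(self, dose: float) -> float:
        """Affected fraction at a dose, fa = 1/(1+(Dm/D)^m)."""
        return 1.0 / (1.0 + (self.Dm / dose) ** self.m)

    def dx(self, fa: float) -> float:
        """Dose required for effect fa: Dm * (fa/(1-fa))^(1/m)."""
        if not 0 < fa < 1:
            raise ValueError("fa must lie strictly in (0, 1)")
        return float(self.Dm * (fa / (1.0 - fa)) ** (1.0 / self.m))


def median_effect_fit(table: pd.DataFrame, drug: str = "") -> MedianEffectFit:
    """Fit the median-effect line to a monotherapy (dose, fa) table.

    Rows with fa outside (0, 1) carry no log-logit information and are
    dropped; at least 3 usable rows are required.
    """
    dose = np.asarray(table["dose"], float)
    fa = np.asarray(table["fa"], float)
    ok = (fa > 0) & (fa < 1) & (dose > 0)
    dose, fa = dose[ok], fa[ok]
    if dose.size < 3:
        raise ValueError(
            f"need >= 3 doses with fa in (0,1); only {dose.size} usable"
        )
    x = np.log(dose)
    y = np.log(fa / (1.0 - fa))
    m, intercept = np.polyfit(x, y, 1)
    if m <= 0:
        raise ValueError(f"non-positive median-effect slope m={m:.3g}")
    Dm = float(np.exp(-intercept / m))
    yhat = m * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return MedianEffectFit(Dm=Dm, m=float(m), drug=drug, r_squared=r2)


def combination_index(
    doses: dict[str, float],
    fa: float,
    fits: dict[str, MedianEffectFit],
) -> float:
    """Non-constant-ratio CI at the combination's observed effect."""
    if not 0 < fa < 1:
        raise ValueError(f"fa={fa} outside (0,1): CI undefined")
    ci = 0.0
    for drug, d in doses.items():
        if d < 0:
            raise ValueError(f"negative dose for {drug}")
        if d == 0:
            continue
        ci += d / fits[drug].dx(fa)
    return float(ci)


def classify_ci(ci: float) -> str:
    if ci <= 0:
        raise ValueError("CI must be positive")
    if ci < CI_STRONG_SYNERGY:
        return "strong synergy"
    if ci < CI_SYNERGY:
        return "synergy"
    if ci <= CI_ANTAGONISM:
        return "additive"
    return "antagonism"


def sample_dose_combinations(
    bounds: dict[str, tuple[float, float]],
    n: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """LHS of n dose vectors, log-uniform within per-drug bounds."""
    return lhs_log_doses(bounds, n, seed)


def average_patient_fa(
    params: ModelParameters,
    regimen: Regimen,
    start_volume: float = 1.77,
    rx_end_day: float = 189.0,
    rtol: float = 1e-6,
    _ctrl_cache: dict = {},
) -> float:
    """fa = end-of-treatment TGI/100 for the average patient, clipped."""
    key = (params.to_array().tobytes(), start_volume, rx_end_day)
    if key not in _ctrl_cache:
        y0 = equilibrium_state(params, start_volume)
        ctrl = simulate(params, None, (0.0, rx_end_day), initial=y0,
                        rtol=rtol, t_eval_step=3.0)
        _ctrl_cache[key] = (y0, float(ctrl.volume[-1]))
    y0, v_ctrl = _ctrl_cache[key]
    tr = simulate(params, regimen, (0.0, rx_end_day), initial=y0,
                  rtol=rtol, t_eval_step=3.0)
    t = compute_tgi(float(tr.volume[-1]), v_ctrl, start_volume)
    return float(np.clip(t / 100.0, *FA_CLIP))


def make_fa_evaluator(
    params: ModelParameters, **kwargs
) -> Callable[[Regimen], float]:
    """Bind :func:`average_patient_fa` to a parameter set."""
    return lambda regimen: average_patient_fa(params, regimen, **kwargs)


def run_combination_study(
    fa_evaluator: Callable[[Regimen], float],
    bounds: dict[str, tuple[float, float]],
    fits: dict[str, MedianEffectFit],
    n: int = 50,
    seed: int = 0,
    schedule: str = "Q3W",
    pfs_evaluator: Callable[[Regimen], float] | None = None,
) -> pd.DataFrame:
    """CI table over an LHS-sampled dose grid for one combination.

    For every sampled dose vector a Q3W course is simulated (cisplatin
    capped at six cycles by the regimen builder), the combined affected
    fraction is measured, and the Chou-Talalay CI and its class are
    recorded.  Per-vector simulation failures are logged and skipped.
    ``pfs_evaluator`` optionally adds a median-PFS column.
    """
    samples = sample_dose_combinations(bounds, n, seed)
    rows = []
    for _, s in samples.iterrows():
        doses = {drug: float(s[drug]) for drug in samples.columns}
        reg = build_regimen(doses, schedule)
        row = dict(doses)
        try:
            fa = fa_evaluator(reg)
            ci = combination_index(doses, fa, fits)
            row.update(fa=fa, ci=ci, ci_class=classify_ci(ci))
            if pfs_evaluator is not None:
                row["median_pfs"] = pfs_evaluator(reg)
        except Exception as exc:
            row.update(fa=np.nan, ci=np.nan, ci_class=f"error: {exc}")
        rows.append(row)
    out = pd.DataFrame(rows)
    valid = out["ci"].notna()
    out.attrs["fraction_synergistic"] = float(
        (out.loc[valid, "ci"] < CI_SYNERGY).sum() / max(int(valid.sum()), 1)
    )
    out.attrs["fraction_strong_synergy"] = float(
        (out.loc[valid, "ci"] < CI_STRONG_SYNERGY).sum() / max(int(valid.sum()), 1)
    )
    return out
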