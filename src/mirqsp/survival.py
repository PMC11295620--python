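"""Progression-free survival analysis: Kaplan-Meier, Cox HR, PFS-dose Hill.

Virtual-trial endpoints follow clinical-oncology convention: each
patient contributes a time-to-progression (months) and an event flag
(progressed vs censored at the simulation horizon).  The product-limit
estimator gives the PFS curve; median PFS is the first time the curve
reaches 0.5; the hazard ratio of treatment vs control comes from a Cox
proportional-hazards fit (Efron tie handling) with a Wald 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

__all__ = [
    "SurvivalCurve",
    "HazardRatioResult",
    "kaplan_meier",
    "median_pfs",
    "hazard_ratio",
    "pfs_dose_hill",
]

#: horizon (months) at which progression-free patients are censored
DEFAULT_HORIZON_MONTHS = 36.0


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function with its source event table."""

    times: np.ndarray          # months, event/censor times of the steps
    survival: np.ndarray       # S(t) just after each step time
    median: float | None       # months; None if S never reaches 0.5
    label: str = ""
    table: pd.DataFrame | None = None

    def probability_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(ttp_table: pd.DataFrame, label: str = "") -> SurvivalCurve:
    """Product-limit PFS estimate from a (time, event) table.

    ``ttp_table`` needs columns ``time`` (months, > 0) and ``event``
    (1 = progression observed, 0 = censored).
    """
    if len(ttp_table) == 0:
        raise ValueError("empty time-to-progression table")
    times = np.asarray(ttp_table["time"], float)
    events = np.asarray(ttp_table["event"], int)
    if np.any(times <= 0):
        raise ValueError("event/censor times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(float)
    s = sf.iloc[:, 0].to_numpy(float)
    med = kmf.median_survival_time_
    median = None if not np.isfinite(med) else float(med)
    return SurvivalCurve(times=t, survival=s, median=median, label=label,
                         table=ttp_table.reset_index(drop=True))


def median_pfs(curve: SurvivalCurve) -> float | None:
    """First time S(t) <= 0.5, in months; None if never reached."""
    return curve.median


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    log_hr_se: float
    separation_flag: bool = False

    def __iter__(self):
        yield from (self.hr, self.ci_low, self.ci_high)


def hazard_ratio(
    treated: pd.DataFrame, control: pd.DataFrame
) -> HazardRatioResult:
    """Cox proportional-hazards HR of progression, treated vs control.

    Both tables carry (time, event) columns as for
    :func:`kaplan_meier`.  With completely separated risk sets the
    partial likelihood has no interior optimum; the estimate is then
    reported at the fitter's boundary with ``separation_flag`` set.
    """
    for name, tab in (("treated", treated), ("control", control)):
        if int(np.asarray(tab["event"]).sum()) < 2:
            raise ValueError(f"{name} group needs >= 2 events for a Cox fit")
    df = pd.concat(
        [
            pd.DataFrame({"time": treated["time"], "event": treated["event"], "arm": 1}),
            pd.DataFrame({"time": control["time"], "event": control["event"], "arm": 0}),
        ],
        ignore_index=True,
    )
    cph = CoxPHFitter()
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception:
            # ridge-stabilized refit for (near-)separated groups
            separation = True
            cph = CoxPHFitter(penalizer=1e-4)
            cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["arm"])
    se = float(cph.standard_errors_["arm"])
    if abs(beta) > 15 or not np.isfinite(se) or se > 50:
        separation = True
    z = 1.959963984540054
    return HazardRatioResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(max(beta - z * se, -700.0))),
        ci_high=float(np.exp(min(beta + z * se, 700.0))),
        log_hr_se=se,
        separation_flag=separation,
    )


def pfs_dose_hill(pfs_table: pd.DataFrame):
    """Hill characterization of median PFS vs dose.

    ``pfs_table`` columns: ``dose`` (mg/kg) and ``median_pfs``
    (months).  The zero-dose (control) PFS enters as the Emin of the
    baseline-shifted Hill form; returns a
    :class:`~mirqsp.dose_response.HillFit`.
    """
    from .dose_response import fit_hill

    tab = pd.DataFrame(
        {"dose": pfs_table["dose"], "effect": pfs_table["median_pfs"]}
    )
    return fit_hill(tab, form="Eq2")
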