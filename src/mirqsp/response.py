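"""Treatment-response metrics: TGI, RECIST 1.1 categories, TTP.

Two complementary endpoints summarize a simulated tumor trajectory:

* tumor growth inhibition (TGI), the fraction of control-arm growth
  abolished by treatment, 100 * (1 - (V_t - V0) / (V_c - V0));
* RECIST 1.1 single-lesion response, evaluated on tumor diameter
  assuming spherical geometry.  Progressive disease (PD) requires a
  diameter at least 20% above the nadir (smallest diameter since
  treatment start, baseline included) AND an absolute increase of at
  least 0.5 cm; partial response (PR) is a diameter at or below 70% of
  baseline; complete response (CR) is disappearance below the imaging
  detection floor.  Time to progression (TTP) is the first PD crossing,
  linearly interpolated between stored points and reported in months
  (30.44 days/month).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DAYS_PER_MONTH",
    "ResponseRecord",
    "tgi",
    "volume_to_diameter",
    "diameter_to_volume",
    "recist_classify",
    "pct_diameter_change",
]

DAYS_PER_MONTH = 30.44

#: below this diameter (cm) a lesion is radiologically undetectable
DETECTION_FLOOR_CM = 0.1


def tgi(V_treated_t: float, V_control_t: float, V0: float) -> float:
    """Tumor growth inhibition (%) at a common evaluation time.

    100% means the treated tumor did not grow at all relative to its
    starting volume; 0% means it matched the control arm; values above
    100% indicate net shrinkage.  Undefined when the control arm did
    not grow.
    """
    if V_control_t <= V0:
        raise ValueError(
            f"control arm did not grow (V_control={V_control_t} <= V0={V0}); "
            "TGI undefined"
        )
    return 100.0 * (1.0 - (V_treated_t - V0) / (V_control_t - V0))


def volume_to_diameter(V: float | np.ndarray) -> float | np.ndarray:
    """Diameter (cm) of a sphere of volume V (cm^3): (6V/pi)^(1/3)."""
    V = np.asarray(V, float)
    if np.any(V < 0):
        raise ValueError("volume must be non-negative")
    out = (6.0 * V / np.pi) ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def diameter_to_volume(d: float | np.ndarray) -> float | np.ndarray:
    """Sphere volume (cm^3) from diameter (cm): pi d^3 / 6."""
    d = np.asarray(d, float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    out = np.pi * d**3 / 6.0
    return float(out) if out.ndim == 0 else out


def pct_diameter_change(diameters: np.ndarray) -> np.ndarray:
    """Percent change of each diameter from the treatment-start baseline."""
    d = np.asarray(diameters, float)
    if d.size == 0 or d[0] <= 0:
        raise ValueError("diameter series must start with a positive baseline")
    return 100.0 * (d - d[0]) / d[0]


@dataclass
class ResponseRecord:
    """RECIST summary of one treated trajectory."""

    times_day: np.ndarray
    categories: list[str]               # per time point, in {CR, PR, SD, PD}
    ttp_months: float | None            # None = censored (no PD in window)
    event: bool                         # True if PD occurred
    best_response: str
    pct_change_final: float
    tgi_percent: float | None = None
    extra: dict = field(default_factory=dict)


def recist_classify(
    diameter_series: np.ndarray,
    times_day: np.ndarray,
    detection_floor: float = DETECTION_FLOOR_CM,
    evaluation_times: np.ndarray | None = None,
) -> ResponseRecord:
    """Classify a diameter time series under RECIST 1.1 and locate TTP.

    The series must start at treatment initiation (its first point is
    the baseline).  By default every stored point is evaluated (dense
    ODE grid); passing ``evaluation_times`` restricts assessment to a
    discrete visit schedule.  PD is absorbing for TTP purposes: the
    reported TTP is the first threshold crossing even if the diameter
    later re-enters the SD band.
    """
    d = np.asarray(diameter_series, float)
    t = np.asarray(times_day, float)
    if d.size == 0:
        raise ValueError("empty diameter series")
    if d.shape != t.shape:
        raise ValueError("diameter and time arrays must align")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")

    discrete_visits = evaluation_times is not None
    if discrete_visits:
        ev = np.asarray(evaluation_times, float)
        d = np.interp(ev, t, d)
        t = ev

    baseline = d[0]
    nadir = np.minimum.accumulate(d)
    pd_threshold = np.maximum(1.2 * nadir, nadir + 0.5)
    is_pd = d >= pd_threshold
    is_cr = d <= detection_floor
    is_pr = d <= 0.7 * baseline

    categories = np.where(is_pd, "PD", np.where(is_cr, "CR", np.where(is_pr, "PR", "SD")))

    ttp_months: float | None = None
    event = False
    idx = np.flatnonzero(is_pd)
    if idx.size:
        i = int(idx[0])
        event = True
        if discrete_visits:
            # progression is recorded at the detecting visit, not
            # back-interpolated between visits
            ttp_day = float(t[i])
        elif i == 0:
            ttp_day = float(t[0])
        else:
            # crossing of the threshold in force just before progression
            th = float(pd_threshold[i - 1])
            ttp_day = float(np.interp(th, [d[i - 1], d[i]], [t[i - 1], t[i]]))
        ttp_months = ttp_day / DAYS_PER_MONTH
        if ttp_months <= 0:
            ttp_months = float(t[min(i, 1)]) / DAYS_PER_MONTH or 1e-9

    order = {"CR": 0, "PR": 1, "SD": 2, "PD": 3}
    best = min(categories, key=lambda c: order[str(c)])
    return ResponseRecord(
        times_day=t,
        categories=[str(c) for c in categories],
        ttp_months=ttp_months,
        event=event,
        best_response=str(best),
        pct_change_final=float(100.0 * (d[-1] - baseline) / baseline),
    )
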