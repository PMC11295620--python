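"""Interspecies allometric scaling, clinical dose conversion, regimens.

Allometric scaling converts a mouse parameter value to its human
equivalent through a body-weight power law, P_h = P_m * (BW_h/BW_m)^A,
with the exponent A chosen by parameter class: -0.25 for rate
constants, 0.75 for clearances, 1 for volumes of distribution.  For
dose scaling two conventions circulate in the pharmacology literature
(-0.25 and the body-surface-area-derived -0.33); both are available
here and the package default is -0.25, which maps the 0.2 mg/kg mouse
dose of anti-miR-155 onto a 0.026 mg/kg human-equivalent dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import ALLOMETRIC_CLASS, ALLOMETRIC_EXPONENTS, ModelParameters

__all__ = [
    "ScalingSpec",
    "Regimen",
    "allometric_scale",
    "scale_parameters",
    "clinical_dose_to_mg_per_kg",
    "build_regimen",
    "preclinical_twice_weekly",
    "SCHEDULE_INTERVAL_DAYS",
    "SCHEDULE_CYCLES",
]

SCHEDULE_INTERVAL_DAYS = {"QW": 7.0, "Q2W": 14.0, "Q3W": 21.0}
#: number of cycles filling a ~six-month treatment course
SCHEDULE_CYCLES = {"QW": 25, "Q2W": 13, "Q3W": 9}
#: cisplatin is capped at six cycles in any regimen, per clinical practice
CISPLATIN_MAX_CYCLES = 6


@dataclass(frozen=True)
class ScalingSpec:
    """One allometric conversion: mouse value, body weights, exponent."""

    P_mouse: float
    BW_m: float = 0.02
    BW_h: float = 70.0
    A: float = -0.25

    def __post_init__(self) -> None:
        if self.BW_m <= 0 or self.BW_h <= 0:
            raise ValueError("body weights must be positive")


def allometric_scale(spec: ScalingSpec) -> float:
    """Return the human-equivalent value P_mouse * (BW_h/BW_m)^A."""
    return spec.P_mouse * (spec.BW_h / spec.BW_m) ** spec.A


def scale_parameters(
    mouse: ModelParameters,
    BW_h: float = 70.0,
    exponents: dict[str, float] | None = None,
) -> ModelParameters:
    """Allometrically scale a full mouse parameter set to a human one.

    Each symbol uses the exponent of its allometric class; class
    ``none`` passes values through unchanged.  This is the mechanical
    conversion only — drug-specific human PK constants are usually
    substituted afterwards from clinical literature.
    """
    exps = dict(ALLOMETRIC_EXPONENTS)
    if exponents:
        exps.update(exponents)
    out: dict[str, float] = {}
    for name, value in mouse:
        klass = ALLOMETRIC_CLASS.get(name, "none")
        spec = ScalingSpec(value, BW_m=mouse.BW, BW_h=BW_h, A=exps[klass])
        out[name] = allometric_scale(spec)
    out["BW"] = BW_h
    return ModelParameters.from_dict(out)


def clinical_dose_to_mg_per_kg(
    dose: float,
    basis: str = "fixed-mg",
    BSA: float = 1.9,
    BW: float = 70.0,
) -> float:
    """Convert a clinically stated dose to mg/kg.

    ``basis='per-m2'`` interprets ``dose`` as mg/m^2 (dose*BSA/BW);
    ``basis='fixed-mg'`` as a flat mg amount (dose/BW);
    ``basis='per-kg'`` passes through.  Default body habitus is a 70 kg
    adult with 1.9 m^2 body surface area.
    """
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    if BSA <= 0 or BW <= 0:
        raise ValueError("BSA and BW must be positive")
    if basis == "per-m2":
        return dose * BSA / BW
    if basis == "fixed-mg":
        return dose / BW
    if basis == "per-kg":
        return dose
    raise ValueError(f"unknown dose basis {basis!r}")


def mouse_dose_ng_to_mg_per_kg(dose_ng: float, BW_kg: float = 0.02) -> float:
    """Convert a per-animal dose in ng to mg/kg (4,000 ng ≡ 0.2 mg/kg)."""
    if dose_ng < 0:
        raise ValueError("dose must be non-negative")
    return dose_ng * 1e-6 / BW_kg


@dataclass
class Regimen:
    """Multi-drug dosing schedule.

    ``doses`` maps drug id -> list of (time_day, dose_mg_per_kg).
    Recognized drug ids: ``antimir``, ``cisplatin``, ``atezolizumab``,
    ``pembrolizumab``.
    """

    doses: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    schedule: str = ""

    def __post_init__(self) -> None:
        for drug, events in self.doses.items():
            times = [t for t, _ in events]
            if any(t < 0 for t in times):
                raise ValueError(f"negative dose time for {drug}")
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"dose times for {drug} must strictly increase")
            if any(d <= 0 for _, d in events):
                raise ValueError(f"doses for {drug} must be positive")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.doses)

    def all_dose_times(self) -> np.ndarray:
        """Sorted unique dose times across drugs."""
        ts: set[float] = set()
        for events in self.doses.values():
            ts.update(t for t, _ in events)
        return np.array(sorted(ts))

    def events_at(self, t: float, tol: float = 1e-9) -> dict[str, float]:
        """Drug -> dose (mg/kg) administered at time t."""
        out = {}
        for drug, events in self.doses.items():
            for td, d in events:
                if abs(td - t) <= tol:
                    out[drug] = out.get(drug, 0.0) + d
        return out

    def last_dose_day(self) -> float:
        times = self.all_dose_times()
        return float(times[-1]) if times.size else 0.0

    def to_frame(self):
        import pandas as pd

        rows = [
            {"drug": drug, "day": t, "dose_mg_per_kg": d}
            for drug, events in self.doses.items()
            for t, d in events
        ]
        return pd.DataFrame(rows, columns=["drug", "day", "dose_mg_per_kg"])


def build_regimen(
    drugs: dict[str, float],
    schedule: str = "Q3W",
    start_day: float = 0.0,
    cycles: int | None = None,
) -> Regimen:
    """Construct a clinical regimen on a QW/Q2W/Q3W grid.

    ``drugs`` maps drug id -> dose in mg/kg.  The cycle count defaults
    to the six-month course for the schedule (QW 25, Q2W 13, Q3W 9);
    cisplatin is truncated to six cycles regardless.
    """
    if schedule not in SCHEDULE_INTERVAL_DAYS:
        raise ValueError(f"unknown schedule {schedule!r}; use QW, Q2W or Q3W")
    interval = SCHEDULE_INTERVAL_DAYS[schedule]
    n = cycles if cycles is not None else SCHEDULE_CYCLES[schedule]
    doses: dict[str, list[tuple[float, float]]] = {}
    for drug, dose in drugs.items():
        if dose <= 0:
            raise ValueError(f"dose for {drug} must be positive")
        n_drug = min(n, CISPLATIN_MAX_CYCLES) if drug == "cisplatin" else n
        doses[drug] = [(start_day + i * interval, dose) for i in range(n_drug)]
    return Regimen(doses=doses, schedule=schedule)


def preclinical_twice_weekly(
    drug: str,
    dose_mg_per_kg: float,
    duration_days: float = 28.0,
    start_day: float = 0.0,
) -> Regimen:
    """Mouse-style twice-a-week schedule (3/4-day alternation)."""
    times = []
    t, step = start_day, 3.0
    while t <= start_day + duration_days + 1e-9:
        times.append(t)
        t += step
        step = 7.0 - step  # alternate 3- and 4-day gaps
    return Regimen(doses={drug: [(t, dose_mg_per_kg) for t in times]}, schedule="BIW")
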