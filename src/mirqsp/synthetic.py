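"""Synthetic-data generators: preclinical tumor-growth arms, toy
survival tables, and known-truth dose-response data.

No experimental datasets ship with this package; every analysis is
driven by data generated from the mechanistic model itself (or, for
unit-level oracles, from closed-form curves).  The preclinical
generator emulates the structure of pooled NSCLC xenograft studies:
five treatment arms (anti-miR-155 nanoparticles twice weekly,
cisplatin weekly, their combination, atezolizumab, pembrolizumab) and
two control arms, with multiplicative lognormal measurement noise on
tumor volumes.  The generating "truth" parameters are stored alongside
the data so calibration can be scored against them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import equilibrium_state, simulate
from .parameters import ModelParameters
from .scaling import Regimen, preclinical_twice_weekly

__all__ = [
    "PreclinicalDataset",
    "default_protocols",
    "generate_preclinical",
    "generate_survival_toy",
    "generate_hill_data",
]

#: measurement schedule (days) for mouse studies, twice weekly for 4 weeks
MEASUREMENT_DAYS = np.array([0.0, 4.0, 7.0, 11.0, 14.0, 18.0, 21.0, 25.0, 28.0])
MOUSE_V0_CM3 = 0.1


def default_protocols() -> dict[str, dict]:
    """The seven-arm preclinical design (two controls, five treatments).

    Mirrors the pooled study structure: anti-miR-155-loaded NPs at
    0.2 mg/kg twice a week; cisplatin at 8 mg/kg once weekly; their
    combination; and the two checkpoint antibodies twice a week.
    """
    cis = Regimen({"cisplatin": [(float(t), 8.0) for t in (0, 7, 14, 21)]})
    am = preclinical_twice_weekly("antimir", 0.2, 28.0)
    return {
        "control-1": {"regimen": None, "v0": MOUSE_V0_CM3, "days": MEASUREMENT_DAYS},
        "control-2": {"regimen": None, "v0": MOUSE_V0_CM3, "days": MEASUREMENT_DAYS},
        "anti-miR-155": {"regimen": am, "v0": MOUSE_V0_CM3, "days": MEASUREMENT_DAYS},
        "cisplatin": {"regimen": cis, "v0": MOUSE_V0_CM3, "days": MEASUREMENT_DAYS},
        "combo": {
            "regimen": Regimen({**am.doses, **cis.doses}),
            "v0": MOUSE_V0_CM3, "days": MEASUREMENT_DAYS,
        },
        "atezolizumab": {
            "regimen": preclinical_twice_weekly("atezolizumab", 10.0, 28.0),
            "v0": MOUSE_V0_CM3, "days": MEASUREMENT_DAYS,
        },
        "pembrolizumab": {
            "regimen": preclinical_twice_weekly("pembrolizumab", 5.0, 28.0),
            "v0": MOUSE_V0_CM3, "days": MEASUREMENT_DAYS,
        },
    }


@dataclass
class PreclinicalDataset:
    """Per-arm tumor-growth summaries plus the generating truth record."""

    arms: dict[str, pd.DataFrame]      # time_day, mean_volume_mm3, sd_mm3, n_animals
    protocols: dict[str, dict]
    truth: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for label, df in self.arms.items():
            d = df.copy()
            d.insert(0, "arm", label)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)

    def save(self, stem: str | Path) -> None:
        """Write <stem>.csv (tidy arm data) and <stem>.json (truth record)."""
        stem = Path(stem)
        self.to_frame().to_csv(stem.with_suffix(".csv"), index=False)
        with open(stem.with_suffix(".json"), "w") as fh:
            json.dump(self.truth, fh, indent=1)

    @classmethod
    def load(cls, stem: str | Path,
             protocols: dict[str, dict] | None = None) -> "PreclinicalDataset":
        stem = Path(stem)
        tidy = pd.read_csv(stem.with_suffix(".csv"))
        arms = {
            label: g.drop(columns="arm").reset_index(drop=True)
            for label, g in tidy.groupby("arm", sort=False)
        }
        with open(stem.with_suffix(".json")) as fh:
            truth = json.load(fh)
        return cls(arms=arms, protocols=protocols or default_protocols(),
                   truth=truth)


def generate_preclinical(
    truth: ModelParameters,
    protocols: dict[str, dict] | None = None,
    noise_cv: float = 0.15,
    n_animals: int = 8,
    seed: int = 0,
    rtol: float = 1e-8,
) -> PreclinicalDataset:
    """Simulate the preclinical arms and add measurement noise.

    Each animal's volume series is the noiseless model trajectory times
    independent lognormal factors with the stated coefficient of
    variation; arm summaries are the cross-animal mean and SD.  With
    ``noise_cv=0`` the dataset equals the noiseless model output
    exactly.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    protocols = protocols or default_protocols()
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    arms: dict[str, pd.DataFrame] = {}
    for label, proto in protocols.items():
        days = np.asarray(proto["days"], float)
        y0 = equilibrium_state(truth, proto["v0"])
        tr = simulate(truth, proto["regimen"], (days[0], days[-1]),
                      initial=y0, rtol=rtol, t_eval_step=1.0)
        model_mm3 = 1000.0 * np.interp(days, tr.t, tr.volume)
        if noise_cv == 0:
            mean, sd = model_mm3, np.zeros_like(model_mm3)
        else:
            factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma,
                                    size=(n_animals, days.size))
            animals = model_mm3[None, :] * factors
            mean = animals.mean(axis=0)
            sd = animals.std(axis=0, ddof=1)
        arms[label] = pd.DataFrame({
            "time_day": days,
            "mean_volume_mm3": mean,
            "sd_mm3": sd,
            "n_animals": n_animals,
        })
    truth_record = {
        "params": truth.to_dict(),
        "noise_cv": noise_cv,
        "n_animals": n_animals,
        "seed": seed,
    }
    return PreclinicalDataset(arms=arms, protocols=protocols, truth=truth_record)


def generate_survival_toy(
    n: int,
    rates: dict[str, float],
    censor_time: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times per group, censored at ``censor_time``.

    The true hazard ratio between any two groups is the ratio of their
    rates; it is stored in ``DataFrame.attrs['rates']``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for group, rate in rates.items():
        if rate <= 0:
            raise ValueError(f"rate for {group} must be positive")
        t = rng.exponential(1.0 / rate, size=n)
        event = t <= censor_time
        frames.append(pd.DataFrame({
            "group": group,
            "time": np.minimum(t, censor_time),
            "event": event.astype(int),
        }))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["rates"] = dict(rates)
    out.attrs["censor_time"] = censor_time
    return out


def generate_hill_data(
    Emax: float,
    EC50: float,
    n: float,
    doses: np.ndarray,
    Emin: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dose-effect table from an exact Hill curve plus Gaussian noise.

    With ``Emin`` given, uses the baseline-shifted form
    E = Emin + (Emax - Emin)/(1 + (EC50/D)^n); otherwise the
    three-parameter saturating form.  The generating truth is stored in
    ``DataFrame.attrs['truth']``.
    """
    doses = np.asarray(doses, float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    frac = 1.0 / (1.0 + (EC50 / doses) ** n)
    effect = Emax * frac if Emin is None else Emin + (Emax - Emin) * frac
    if noise_sd > 0:
        effect = effect + np.random.default_rng(seed).normal(0, noise_sd,
                                                             doses.size)
    out = pd.DataFrame({"dose": doses, "effect": effect})
    out.attrs["truth"] = {"Emax": Emax, "EC50": EC50, "n": n, "Emin": Emin,
                          "noise_sd": noise_sd, "seed": seed}
    return out
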