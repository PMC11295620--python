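"""Model parameters for the anti-miR-155 tumor-immune QSP model.

Every rate, binding constant, and physiological quantity used by the
mechanistic model lives in :class:`ModelParameters`.  Two complete
baseline sets are provided (mouse and human); each symbol carries an
allometric class that controls how mouse values are extrapolated to
humans when an explicit human value is not supplied.

Unit conventions used throughout the package: time in days, drug mass
in mg, volumes in mL (== cm^3 for tumor), nanoparticle-cargo
concentrations in mg/mL, molecular species (miR-155, PD-L1, PD-1,
antibodies in tumor) in pM.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "ALLOMETRIC_CLASS",
    "ALLOMETRIC_EXPONENTS",
    "mouse_defaults",
    "human_defaults",
    "load_parameter_table",
    "save_parameter_table",
]

#: Allometric exponent applied per parameter class when scaling
#: mouse -> human as P_h = P_m * (BW_h / BW_m)^A.
ALLOMETRIC_EXPONENTS: dict[str, float] = {
    "rate": -0.25,
    "clearance": 0.75,
    "volume": 1.0,
    # The human-equivalent-dose worked example (0.2 mg/kg mouse ->
    # 0.026 mg/kg human for a 0.02 -> 70 kg conversion) corresponds to
    # exponent -0.25; the conventional body-surface-area dose exponent
    # -0.33 is also selectable via ``allometric_scale``.
    "dose": -0.25,
    "none": 0.0,
}


@dataclass
class ModelParameters:
    """Complete parameter set for one species / one virtual subject.

    Attributes are grouped by the biological process they control; see
    ``docs/methods.md`` for the governing equations.
    """

    # --- tumor growth & miR-155 pharmacodynamics -------------------------
    gamma: float = 0.055383       # intrinsic tumor proliferation rate, 1/day
    A_ML: float = 2.283516        # miR-155 proliferation stimulation coefficient (>1)
    k_M: float = 0.7              # Michaelis constant (potency) of miR-155 effects, pM
    g0_M_c: float = 1.2           # miR-155 production rate in cancer cells, pM/day
    g0_M_t: float = 1.8           # miR-155 production rate in TAMs, pM/day
    delta_M: float = 1.0          # miR-155 degradation rate, 1/day
    k_exo: float = 0.2            # TAM->cancer exosomal miR-155 transfer rate, 1/day
    K: float = 3.0                # tumor carrying capacity, cm^3

    # --- anti-miR-155 action ---------------------------------------------
    A_AM_M: float = 150.0         # fold-enhancement of miR-155 degradation (>1)
    delta_AM: float = 0.30        # intracellular anti-miR-155 degradation, 1/day
    EC50_AM: float = 1.156e-2     # anti-miR-155 half-effect concentration, mg/mL

    # --- nanoparticle PK & intratumoral transport ------------------------
    k_Cl: float = 2.0             # NP hepatobiliary clearance from plasma, 1/day
    delta_NP: float = 1.0         # NP metabolic degradation rate, 1/day
    P_NP: float = 0.1             # tumor microvascular permeability to NPs, cm/day
    S0: float = 100.0             # reference microvascular area per tumor volume, 1/cm
    V_ref: float = 0.2            # tumor volume at which S = S0, cm^3
    Len: float = 0.01             # intercapillary diffusion length, cm
    Phi_NP: float = 100.0         # NP diameter, nm (reference 100 nm)
    D_NP: float = 8.6e-3          # NP interstitial diffusivity, cm^2/day
    k_up: float = 5.0             # cellular NP uptake rate, 1/day

    # --- cisplatin ---------------------------------------------------------
    delta_chemo: float = 0.309768 # maximal cisplatin-induced death rate, 1/day
    EC50_cis: float = 2.0e-2      # cisplatin half-effect concentration, mg/mL
    A_MR: float = 4.0             # miR-155 chemoresistance coefficient
    k_cl_cis: float = 2.0         # cisplatin plasma clearance, 1/day
    k_dist_cis: float = 10.0      # plasma<->tumor cisplatin distribution rate, 1/day

    # --- immune compartment & checkpoint ----------------------------------
    delta_immun: float = 0.022182 # maximal CD8+ T-cell killing rate, 1/day
    g_L: float = 8.5              # PD-L1 synthesis rate, pM/day
    delta_L: float = 1.0          # PD-L1 turnover, 1/day
    k_ML: float = 0.2             # miR-155 repression constant for PD-L1, pM
    g_P: float = 1.0              # PD-1 synthesis rate on T cells, pM/day
    delta_P: float = 1.0          # PD-1 turnover, 1/day (equilibrium g_P/delta_P = 1 pM)
    Kd_PDL1: float = 1.0 / 3.0    # PD-1:PD-L1 dissociation constant, pM
    Kd_ate: float = 3.515e5       # atezolizumab:PD-L1 dissociation constant, pM
    Kd_pem: float = 5.0e4         # pembrolizumab:PD-1 dissociation constant, pM
    rho_T: float = 1.0e8          # TAM recruitment density, cells/cm^3
    rho_M8: float = 1.0e7         # CD8+ T-cell recruitment density, cells/cm^3
    V_sat_T8: float = 1.0         # tumor volume at which T-cell recruitment saturates, cm^3
    K_rho8: float = 2.5e6         # half-saturation effector density for killing, cells/cm^3
    k_rec: float = 1.0            # immune-population relaxation rate, 1/day

    # --- antibody PK -------------------------------------------------------
    k_cl_ate: float = 0.14        # atezolizumab plasma clearance, 1/day
    k_cl_pem: float = 0.14        # pembrolizumab plasma clearance, 1/day
    k_dist_ab: float = 1.0        # plasma->tumor antibody distribution rate, 1/day
    MW_ate: float = 1.45e5        # atezolizumab molecular weight, g/mol
    MW_pem: float = 1.49e5        # pembrolizumab molecular weight, g/mol

    # --- physiology --------------------------------------------------------
    V_pl: float = 1.0             # plasma volume, mL
    BW: float = 0.02              # body weight, kg
    phi_int: float = 0.3          # tumor interstitial volume fraction
    f_cell: float = 0.6           # cancer-cell volume fraction of tumor
    f_TAM_uptake: float = 0.1     # fraction of NP uptake going to TAMs
    cells_per_cm3: float = 1.0e9  # cancer-cell number density, cells/cm^3

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    _POSITIVE = None  # filled below

    def validate(self) -> None:
        """Raise ``ValueError`` on non-physical values."""
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v}")
            if v <= 0 and f.name not in ():
                raise ValueError(f"parameter {f.name} must be positive, got {v}")
        if self.A_ML < 1.0:
            raise ValueError(f"A_ML must be >= 1, got {self.A_ML}")
        if self.A_AM_M < 1.0:
            raise ValueError(f"A_AM_M must be >= 1, got {self.A_AM_M}")
        for frac in ("phi_int", "f_cell", "f_TAM_uptake"):
            v = getattr(self, frac)
            if not 0 < v < 1:
                raise ValueError(f"{frac} must lie in (0, 1), got {v}")

    # -- convenience -----------------------------------------------------
    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given symbols overridden."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    def to_array(self) -> np.ndarray:
        """Dense vector of parameter values in declaration order."""
        return np.array([getattr(self, f.name) for f in fields(self)], float)

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        unknown = set(d) - set(cls.names())
        if unknown:
            raise KeyError(f"unknown parameter symbols: {sorted(unknown)}")
        return cls(**d)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        for f in fields(self):
            yield f.name, getattr(self, f.name)


#: Allometric class per symbol (symbols absent here scale as "none").
ALLOMETRIC_CLASS: dict[str, str] = {
    "gamma": "rate",
    "delta_M": "none",
    "g0_M_c": "none",
    "g0_M_t": "none",
    "k_exo": "none",
    "k_Cl": "rate",
    "delta_NP": "rate",
    "k_up": "rate",
    "delta_AM": "none",
    "delta_chemo": "rate",
    "k_cl_cis": "rate",
    "delta_immun": "rate",
    "k_cl_ate": "none",
    "k_cl_pem": "none",
    "V_pl": "volume",
    "K": "volume",
    "V_ref": "volume",
    "V_sat_T8": "volume",
}


def mouse_defaults() -> ModelParameters:
    """Baseline parameter set for tumor-bearing mice.

    Chosen so the untreated miR-155 pool equilibrates near 1.5 pM in
    cancer cells and TAMs, PD-1 equilibrates at 1 pM, a subcutaneous
    xenograft grows from ~100 mm^3 toward ~1 cm^3 over four weeks, and
    the five preclinical treatment arms produce the graded tumor growth
    inhibition ordering combo > anti-miR > cisplatin > ICIs.
    """
    return ModelParameters()


def human_defaults() -> ModelParameters:
    """Baseline parameter set for an average adult patient (70 kg).

    Rate-class symbols follow the (BW_h/BW_m)^-0.25 allometric
    conversion from the mouse baseline; physiology (plasma volume,
    carrying capacity) uses adult values.  Pharmacodynamic couplings
    (gamma, A_ML, delta_immun, delta_chemo) and drug-specific PK
    constants (antibody and cisplatin clearance, intracellular anti-miR
    turnover) are recalibrated to clinical time-to-progression
    benchmarks rather than mechanically scaled, mirroring the standard
    translational-modeling practice of adjusting scaled parameters
    against observed human endpoints.
    """
    m = mouse_defaults()
    rate = (70.0 / 0.02) ** -0.25  # ~0.1299
    return m.replace(
        BW=70.0,
        V_pl=3000.0,
        K=400.0,
        V_ref=2.0,
        V_sat_T8=20.0,
        gamma=0.001702,
        A_ML=23.794,
        k_Cl=m.k_Cl * rate,
        delta_NP=m.delta_NP * rate,
        k_up=m.k_up * rate,
        delta_chemo=0.415845,
        k_cl_cis=1.0,
        delta_immun=0.039887,
        delta_AM=0.35,
        k_cl_ate=0.033,
        k_cl_pem=0.033,
    )


# ---------------------------------------------------------------------------
# Parameter-table I/O
# ---------------------------------------------------------------------------

def save_parameter_table(path, mouse: ModelParameters, human: ModelParameters) -> None:
    """Write a two-species parameter table as YAML.

    Layout: one block per symbol with ``value_mouse``, ``value_human``,
    ``units`` and ``allometric_class`` keys.
    """
    units = _UNITS
    table = []
    for name in ModelParameters.names():
        table.append(
            {
                "symbol": name,
                "value_mouse": float(getattr(mouse, name)),
                "value_human": float(getattr(human, name)),
                "units": units.get(name, "dimensionless"),
                "allometric_class": ALLOMETRIC_CLASS.get(name, "none"),
            }
        )
    with open(path, "w") as fh:
        yaml.safe_dump({"parameters": table}, fh, sort_keys=False)


def load_parameter_table(path) -> tuple[ModelParameters, ModelParameters]:
    """Load a two-species YAML parameter table; returns (mouse, human).

    Every symbol of :class:`ModelParameters` must be present for both
    species.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rows = doc["parameters"]
    mouse_d = {r["symbol"]: float(r["value_mouse"]) for r in rows}
    human_d = {r["symbol"]: float(r["value_human"]) for r in rows}
    missing = set(ModelParameters.names()) - set(mouse_d)
    if missing:
        raise KeyError(f"parameter table missing symbols: {sorted(missing)}")
    return ModelParameters.from_dict(mouse_d), ModelParameters.from_dict(human_d)


_UNITS: dict[str, str] = {
    "gamma": "1/day", "A_ML": "dimensionless", "k_M": "pM",
    "g0_M_c": "pM/day", "g0_M_t": "pM/day", "delta_M": "1/day",
    "k_exo": "1/day", "K": "cm^3", "A_AM_M": "dimensionless",
    "delta_AM": "1/day", "EC50_AM": "mg/mL", "k_Cl": "1/day",
    "delta_NP": "1/day", "P_NP": "cm/day", "S0": "1/cm", "V_ref": "cm^3",
    "Len": "cm", "Phi_NP": "nm", "D_NP": "cm^2/day", "k_up": "1/day",
    "delta_chemo": "1/day", "EC50_cis": "mg/mL", "A_MR": "dimensionless",
    "k_cl_cis": "1/day", "k_dist_cis": "1/day", "delta_immun": "1/day",
    "g_L": "pM/day", "delta_L": "1/day", "k_ML": "pM", "g_P": "pM/day",
    "delta_P": "1/day", "Kd_PDL1": "pM", "Kd_ate": "pM", "Kd_pem": "pM",
    "rho_T": "cells/cm^3", "rho_M8": "cells/cm^3", "V_sat_T8": "cm^3",
    "K_rho8": "cells/cm^3", "k_rec": "1/day", "k_cl_ate": "1/day",
    "k_cl_pem": "1/day", "k_dist_ab": "1/day", "MW_ate": "g/mol",
    "MW_pem": "g/mol", "V_pl": "mL", "BW": "kg", "phi_int": "fraction",
    "f_cell": "fraction", "f_TAM_uptake": "fraction",
    "cells_per_cm3": "cells/cm^3",
}
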