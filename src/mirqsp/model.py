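"""Multiscale tumor-immune ODE model with nanoparticle and free-drug PK.

The model couples four scales in two compartments (plasma, tumor):

* systemic PK — nanoparticle (NP) mass in plasma is lost to
  hepatobiliary clearance (k_Cl) and metabolic degradation (delta_NP),
  and extravasates into the tumor interstitium across the microvascular
  wall; free cisplatin and checkpoint antibodies clear first-order from
  plasma and equilibrate with tumor effect compartments;
* intratumoral transport — transvascular NP flux is
  P_NP * S(V) * V * (C_plasma - C_interstitium) with the vascular
  surface density S(V) = S0 * (V/V_ref)^(-1/3), so larger tumors expose
  relatively less exchange area; interstitial NPs then diffuse over a
  characteristic intercapillary length and are taken up by cells at the
  serial rate 1/(Len^2/D_NP + 1/k_up);
* molecular pharmacodynamics — intracellular anti-miR-155 multiplies
  the miR-155 degradation rate by 1 + (A_AM_M - 1) * AM/(EC50_AM + AM);
  miR-155 stimulates proliferation through
  1 + (A_ML - 1) * M/(k_M + M), raises the effective cisplatin EC50
  (chemoresistance), and represses PD-L1 synthesis through
  k_ML/(k_ML + M); PD-1:PD-L1 occupancy at quasi-equilibrium, reduced
  competitively by free antibody, scales down CD8+ T-cell killing;
* tumor growth — logistic growth minus chemotherapy- and
  immune-mediated death terms.

All state components are non-negative and NP mass is conserved:
injected = plasma + interstitium + cumulative sinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import ModelParameters
from .scaling import Regimen

__all__ = [
    "STATE_NAMES",
    "SimulationError",
    "PatientRejected",
    "Trajectory",
    "evaluate_derivatives",
    "equilibrium_state",
    "simulate",
    "grow_to_treatment_start",
    "percent_injected_dose",
    "SINGLE_CELL_VOLUME",
]

STATE_NAMES = [
    "NP_plasma",        # mg
    "NP_interstitium",  # mg
    "NP_sink",          # mg, cumulative cleared/degraded/internalized
    "AM_cancer",        # mg/mL
    "AM_TAM",           # mg/mL
    "M_cancer",         # pM
    "M_TAM",            # pM
    "L_cancer",         # pM
    "L_TAM",            # pM
    "P_Tcell",          # pM
    "Cis_plasma",       # mg
    "Cis_tumor",        # mg/mL
    "AbA_plasma",       # mg  (atezolizumab)
    "AbA_tumor",        # pM
    "AbP_plasma",       # mg  (pembrolizumab)
    "AbP_tumor",        # pM
    "V_tumor",          # cm^3
    "N_TAM",            # cells
    "N_T8",             # cells
]
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)

#: volume of a single cancer cell at 1e9 cells/cm^3
SINGLE_CELL_VOLUME = 1e-9  # cm^3

# map drug id -> plasma state receiving the bolus
_DOSE_STATE = {
    "antimir": _IDX["NP_plasma"],
    "cisplatin": _IDX["Cis_plasma"],
    "atezolizumab": _IDX["AbA_plasma"],
    "pembrolizumab": _IDX["AbP_plasma"],
}


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails to converge on an interval."""


class PatientRejected(RuntimeError):
    """Raised when an untreated tumor cannot reach its target volume."""


def checkpoint_occupancy(L: float, abA: float, abP: float, p: ModelParameters) -> float:
    """Fraction of PD-1 occupied by PD-L1 at binding quasi-equilibrium.

    Free antibody competes with the PD-1:PD-L1 interaction: atezolizumab
    sequesters PD-L1 (Kd_ate) and pembrolizumab blocks PD-1 (Kd_pem),
    reducing the ligand concentration effectively available for
    checkpoint engagement.
    """
    L_eff = L / ((1.0 + abA / p.Kd_ate) * (1.0 + abP / p.Kd_pem))
    return L_eff / (L_eff + p.Kd_PDL1)


def evaluate_derivatives(
    state: np.ndarray, t: float, params: ModelParameters, regimen_context=None
) -> np.ndarray:
    """Time derivative of every state component (units per day).

    Bolus dosing is handled by state jumps in :func:`simulate`;
    ``regimen_context`` is accepted for interface completeness but the
    vector field itself is autonomous between doses.
    """
    p = params
    y = state
    if not np.all(np.isfinite(y)):
        raise SimulationError(f"non-finite state at t={t}")

    (NP_pl, NP_int, _NP_sink, AM_c, AM_t, M_c, M_t, L_c, L_t, P8,
     Cis_pl, Cis_tu, AbA_pl, AbA_tu, AbP_pl, AbP_tu, V, N_TAM, N_T8) = y

    # guard tiny solver undershoot in nonlinear terms
    V = max(V, SINGLE_CELL_VOLUME)
    AM_c = max(AM_c, 0.0); AM_t = max(AM_t, 0.0)
    M_c = max(M_c, 0.0); M_t = max(M_t, 0.0)
    NP_int_pos = max(NP_int, 0.0)

    d = np.empty(N_STATES)

    # --- nanoparticle PK and transport ---------------------------------
    size_factor = 100.0 / p.Phi_NP          # Stokes-Einstein-like size scaling
    P_eff = p.P_NP * size_factor
    S = p.S0 * (V / p.V_ref) ** (-1.0 / 3.0)
    C_pl = NP_pl / p.V_pl
    C_int = NP_int_pos / (p.phi_int * V)
    J = P_eff * S * V * (C_pl - C_int)      # mg/day, can be negative
    k_diff = p.D_NP * size_factor / (p.Len * p.Len)
    k_del = 1.0 / (1.0 / k_diff + 1.0 / p.k_up)
    d[0] = -(p.k_Cl + p.delta_NP) * NP_pl - J
    d[1] = J - (p.delta_NP + k_del) * NP_int
    d[2] = (p.k_Cl + p.delta_NP) * NP_pl + (p.delta_NP + k_del) * NP_int

    # --- intracellular anti-miR-155 ------------------------------------
    U = k_del * NP_int_pos                  # internalized cargo mass, mg/day
    V_cancer = p.f_cell * V                 # mL of cancer-cell cytosol
    V_tam = max(1.0 - p.f_cell - p.phi_int, 1e-6) * V
    d[3] = (1.0 - p.f_TAM_uptake) * U / V_cancer - p.delta_AM * AM_c
    d[4] = p.f_TAM_uptake * U / V_tam - p.delta_AM * AM_t

    # --- miR-155 ---------------------------------------------------------
    deg_c = p.delta_M * (1.0 + (p.A_AM_M - 1.0) * AM_c / (p.EC50_AM + AM_c))
    deg_t = p.delta_M * (1.0 + (p.A_AM_M - 1.0) * AM_t / (p.EC50_AM + AM_t))
    d[5] = p.g0_M_c + p.k_exo * M_t - deg_c * M_c
    d[6] = p.g0_M_t - deg_t * M_t - p.k_exo * M_t

    # --- PD-L1 / PD-1 ----------------------------------------------------
    d[7] = p.g_L * p.k_ML / (p.k_ML + M_c) - p.delta_L * L_c
    d[8] = p.g_L * p.k_ML / (p.k_ML + M_t) - p.delta_L * L_t
    d[9] = p.g_P - p.delta_P * P8

    # --- free-drug PK ----------------------------------------------------
    d[10] = -p.k_cl_cis * Cis_pl
    d[11] = p.k_dist_cis * (Cis_pl / p.V_pl - Cis_tu)
    d[12] = -p.k_cl_ate * AbA_pl
    d[13] = p.k_dist_ab * (1e12 * AbA_pl / (p.MW_ate * p.V_pl) - AbA_tu)
    d[14] = -p.k_cl_pem * AbP_pl
    d[15] = p.k_dist_ab * (1e12 * AbP_pl / (p.MW_pem * p.V_pl) - AbP_tu)

    # --- immune populations ---------------------------------------------
    d[17] = p.k_rec * (p.rho_T * V - N_TAM)
    target_T8 = p.rho_M8 * V / (1.0 + V / p.V_sat_T8)
    d[18] = p.k_rec * (target_T8 - N_T8)

    # --- tumor growth ----------------------------------------------------
    mir_frac = M_c / (p.k_M + M_c)
    gamma_eff = p.gamma * (1.0 + (p.A_ML - 1.0) * mir_frac)
    EC50_eff = p.EC50_cis * (1.0 + p.A_MR * mir_frac)
    kill_chemo = p.delta_chemo * max(Cis_tu, 0.0) / (EC50_eff + max(Cis_tu, 0.0)) * V
    L_mean = 0.5 * (max(L_c, 0.0) + max(L_t, 0.0))
    f_PD = checkpoint_occupancy(L_mean, max(AbA_tu, 0.0), max(AbP_tu, 0.0), p)
    rho8 = max(N_T8, 0.0) / V
    kill_immune = p.delta_immun * rho8 / (rho8 + p.K_rho8) * (1.0 - f_PD) * V
    d[16] = gamma_eff * V * (1.0 - V / p.K) - kill_chemo - kill_immune

    return d


def equilibrium_state(params: ModelParameters, V: float) -> np.ndarray:
    """Untreated steady state of the molecular subsystem at tumor volume V.

    miR-155 settles at its production/turnover balance (TAM pool
    g0_M_t/(delta_M + k_exo); cancer pool fed additionally by exosomal
    transfer), PD-L1 at its miR-repressed synthesis/turnover ratio, and
    PD-1 at g_P/delta_P.  Drug states are zero.
    """
    p = params
    y = np.zeros(N_STATES)
    M_t = p.g0_M_t / (p.delta_M + p.k_exo)
    M_c = (p.g0_M_c + p.k_exo * M_t) / p.delta_M
    y[_IDX["M_cancer"]] = M_c
    y[_IDX["M_TAM"]] = M_t
    y[_IDX["L_cancer"]] = p.g_L * p.k_ML / (p.k_ML + M_c) / p.delta_L
    y[_IDX["L_TAM"]] = p.g_L * p.k_ML / (p.k_ML + M_t) / p.delta_L
    y[_IDX["P_Tcell"]] = p.g_P / p.delta_P
    y[_IDX["V_tumor"]] = V
    y[_IDX["N_TAM"]] = p.rho_T * V
    y[_IDX["N_T8"]] = p.rho_M8 * V / (1.0 + V / p.V_sat_T8)
    return y


@dataclass
class Trajectory:
    """Dense solution of one simulation, with the dosing event log."""

    t: np.ndarray                      # days, strictly increasing
    y: np.ndarray                      # (n_states, n_times)
    params: ModelParameters
    dose_log: list[tuple[float, str, float]] = field(default_factory=list)
    # (time_day, drug, dose_mg_per_kg)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory time grid must strictly increase")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.y[_IDX[name]]

    @property
    def volume(self) -> np.ndarray:
        return self.y[_IDX["V_tumor"]]

    def final_state(self) -> np.ndarray:
        return self.y[:, -1].copy()

    def value_at(self, name: str, t: float) -> float:
        return float(np.interp(t, self.t, self[name]))

    def injected_mass(self, drug: str = "antimir") -> np.ndarray:
        """Cumulative injected mass (mg) of a drug on the time grid."""
        out = np.zeros_like(self.t)
        for td, d, dose in self.dose_log:
            if d == drug:
                out += np.where(self.t >= td - 1e-9, dose * self.params.BW, 0.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time_day, variable, value)."""
        frames = []
        for i, name in enumerate(STATE_NAMES):
            frames.append(
                pd.DataFrame(
                    {"time_day": self.t, "variable": name, "value": self.y[i]}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def dose_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dose_log, columns=["time_day", "drug", "dose_mg_per_kg"]
        )


_EMPTY_REGIMEN = Regimen()


def _atol_vector() -> np.ndarray:
    """Per-state absolute tolerances reflecting typical magnitudes."""
    scale = {
        "NP_plasma": 1e-12, "NP_interstitium": 1e-12, "NP_sink": 1e-12,
        "AM_cancer": 1e-12, "AM_TAM": 1e-12,
        "M_cancer": 1e-10, "M_TAM": 1e-10,
        "L_cancer": 1e-10, "L_TAM": 1e-10, "P_Tcell": 1e-10,
        "Cis_plasma": 1e-12, "Cis_tumor": 1e-14,
        "AbA_plasma": 1e-12, "AbA_tumor": 1e-8,
        "AbP_plasma": 1e-12, "AbP_tumor": 1e-8,
        "V_tumor": 1e-12, "N_TAM": 1e-2, "N_T8": 1e-2,
    }
    return np.array([scale[n] for n in STATE_NAMES])


def simulate(
    params: ModelParameters,
    regimen: Regimen | None = None,
    t_span: tuple[float, float] = (0.0, 28.0),
    initial: np.ndarray | None = None,
    rtol: float = 1e-8,
    t_eval_step: float = 1.0,
    events=None,
) -> Trajectory:
    """Integrate the model over ``t_span`` under a dosing regimen.

    Boluses are exact state jumps (dose_mg_per_kg * BW added to the
    drug's plasma state) with the stiff integrator restarted at every
    dose time.  Raises :class:`SimulationError` naming the failing
    interval if the solver does not converge.
    """
    regimen = regimen or _EMPTY_REGIMEN
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    dose_times = [t for t in regimen.all_dose_times() if t0 <= t <= t1]
    if regimen.doses and any(t < t0 or t > t1 for t in regimen.all_dose_times()):
        raise ValueError("regimen dose times must lie within t_span")

    y = (
        initial.copy()
        if initial is not None
        else equilibrium_state(params, SINGLE_CELL_VOLUME)
    )
    if y.shape != (N_STATES,):
        raise ValueError(f"initial state must have {N_STATES} components")
    if np.any(y < -1e-12):
        raise ValueError("initial state has negative components")

    atol = _atol_vector()
    breakpoints = sorted({t0, t1, *dose_times})
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    dose_log: list[tuple[float, str, float]] = []
    terminated = False

    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        for drug, dose in regimen.events_at(a).items():
            y[_DOSE_STATE[drug]] += dose * params.BW
            dose_log.append((a, drug, dose))
        if terminated:
            break
        n_pts = max(2, int(math.ceil((b - a) / t_eval_step)) + 1)
        t_eval = np.linspace(a, b, n_pts)
        sol = solve_ivp(
            lambda t, yy: evaluate_derivatives(yy, t, params),
            (a, b),
            y,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            t_eval=t_eval,
            events=events,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed on [{a:.3f}, {b:.3f}] days: {sol.message}"
            )
        ts.append(sol.t)
        ys.append(sol.y)
        if sol.status == 1:  # terminal event fired
            ev_t = sol.t_events[0][-1]
            ev_y = sol.y_events[0][-1]
            ts.append(np.array([ev_t]))
            ys.append(ev_y[:, None])
            terminated = True
            y = ev_y.copy()
        else:
            y = sol.y[:, -1].copy()

    # handle doses scheduled exactly at t1
    for drug, dose in regimen.events_at(t1).items():
        if not terminated:
            y[_DOSE_STATE[drug]] += dose * params.BW
            dose_log.append((t1, drug, dose))

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    # at dose times two samples coincide; keep the post-bolus one
    keep = np.concatenate((np.diff(t_all) > 1e-12, [True]))
    t_all, y_all = t_all[keep], y_all[:, keep]
    if not terminated:
        y_all[:, -1] = y  # include any final-instant bolus

    # project solver undershoot onto the admissible orthant
    floor = -1e-6 * np.maximum(np.abs(y_all).max(axis=1, keepdims=True), 1.0)
    if np.any(y_all < floor):
        bad = [STATE_NAMES[i] for i in np.unique(np.where(y_all < floor)[0])]
        raise SimulationError(f"negative state beyond tolerance in {bad}")
    np.clip(y_all, 0.0, None, out=y_all)

    return Trajectory(t=t_all, y=y_all, params=params, dose_log=dose_log)


def grow_to_treatment_start(
    params: ModelParameters,
    target_volume: float | None = None,
    elapsed_days: float | None = None,
    initial_volume: float = SINGLE_CELL_VOLUME,
    cap_days: float = 3650.0,
    rtol: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """Untreated growth from ``initial_volume`` to a stopping point.

    Returns ``(state, elapsed_days)`` at the first time the tumor
    reaches ``target_volume`` (root located by the solver's event
    machinery, well within 0.01 day) or at a fixed ``elapsed_days``.
    Raises :class:`PatientRejected` if the target is not reached within
    ``cap_days`` (default ten years).
    """
    if (target_volume is None) == (elapsed_days is None):
        raise ValueError("specify exactly one of target_volume / elapsed_days")
    y0 = equilibrium_state(params, initial_volume)

    if elapsed_days is not None:
        traj = simulate(params, None, (0.0, elapsed_days), initial=y0,
                        rtol=rtol, t_eval_step=5.0)
        return traj.final_state(), float(elapsed_days)

    if not initial_volume < target_volume < params.K:
        if abs(target_volume - initial_volume) < 1e-15:
            return y0, 0.0
        raise ValueError(
            f"target volume {target_volume} outside ({initial_volume}, K={params.K})"
        )

    iv = _IDX["V_tumor"]

    def hit(t, y):
        return y[iv] - target_volume

    hit.terminal = True
    hit.direction = 1
    traj = simulate(params, None, (0.0, cap_days), initial=y0,
                    rtol=rtol, t_eval_step=10.0, events=hit)
    if traj.volume[-1] < target_volume * (1 - 1e-6):
        raise PatientRejected(
            f"tumor reached only {traj.volume[-1]:.3g} cm^3 of target "
            f"{target_volume:.3g} cm^3 within {cap_days:.0f} days"
        )
    return traj.final_state(), float(traj.t[-1])


def percent_injected_dose(
    trajectory: Trajectory, compartment: str, drug: str = "antimir"
) -> np.ndarray:
    """Percent of cumulatively injected dose present in a compartment.

    Undefined (NaN) before the first dose; bounded in [0, 100] by NP
    mass conservation afterwards.
    """
    if not any(d == drug for _, d, _ in trajectory.dose_log):
        raise ValueError(f"no {drug} dose administered in this trajectory")
    injected = trajectory.injected_mass(drug)
    mass = trajectory[compartment]
    with np.errstate(divide="ignore", invalid="ignore"):
        pid = 100.0 * mass / injected
    pid[injected <= 0] = np.nan
    return pid
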