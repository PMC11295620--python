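"""Core ODE model: closed-form limits, conservation, equilibria."""

import numpy as np
import pytest

from mirqsp.model import (
    STATE_NAMES,
    PatientRejected,
    equilibrium_state,
    evaluate_derivatives,
    grow_to_treatment_start,
    percent_injected_dose,
    simulate,
)
from mirqsp.scaling import Regimen, build_regimen, preclinical_twice_weekly

IDX = {n: i for i, n in enumerate(STATE_NAMES)}


def bolus(drug, dose, day=0.0):
    return Regimen({drug: [(day, dose)]})


class TestDerivatives:
    def test_plasma_only_np_decay(self, mouse_params):
        """Without tumor exchange the plasma NP loss is (k_Cl+delta_NP)*N."""
        p = mouse_params.replace(P_NP=1e-15)
        y = equilibrium_state(p, 0.1)
        y[IDX["NP_plasma"]] = 0.004
        d = evaluate_derivatives(y, 0.0, p)
        expected = -(p.k_Cl + p.delta_NP) * 0.004
        assert d[IDX["NP_plasma"]] == pytest.approx(expected, rel=1e-9)

    def test_transvascular_flux_form(self, mouse_params):
        """Flux follows P*S(V)*V*(C_pl - C_int) with S ~ V^(-1/3)."""
        p = mouse_params.replace(Phi_NP=100.0)
        V = 0.4
        y = equilibrium_state(p, V)
        y[IDX["NP_plasma"]] = 0.004
        d = evaluate_derivatives(y, 0.0, p)
        S = p.S0 * (V / p.V_ref) ** (-1 / 3)
        J = p.P_NP * S * V * (0.004 / p.V_pl - 0.0)
        expected = -(p.k_Cl + p.delta_NP) * 0.004 - J
        assert d[IDX["NP_plasma"]] == pytest.approx(expected, rel=1e-9)

    def test_no_drug_leaves_mir_at_equilibrium(self, mouse_params):
        """With AM=0 the degradation multiplier is 1 and M* = production/turnover."""
        y = equilibrium_state(mouse_params, 0.1)
        d = evaluate_derivatives(y, 0.0, mouse_params)
        for name in ("M_cancer", "M_TAM", "L_cancer", "L_TAM", "P_Tcell"):
            assert abs(d[IDX[name]]) < 1e-10

    def test_mir_equilibrium_near_1p5_pM(self, mouse_params):
        """Pre-treatment miR-155 saturates to ~1.5 pM in both cell pools."""
        y = equilibrium_state(mouse_params, 0.1)
        assert y[IDX["M_cancer"]] == pytest.approx(1.5, abs=0.05)
        assert y[IDX["M_TAM"]] == pytest.approx(1.5, abs=0.05)
        assert y[IDX["P_Tcell"]] == pytest.approx(1.0, rel=1e-12)


class TestSimulate:
    def test_exponential_growth_limit(self, growth_only_mouse, exp_growth_rate):
        """Zero dose, death off, V << K: V(t) = V0 exp(gamma_eff t)."""
        v0 = 0.01
        tr = simulate(growth_only_mouse, None, (0.0, 20.0),
                      initial=equilibrium_state(growth_only_mouse, v0))
        expected = v0 * np.exp(exp_growth_rate * tr.t)
        np.testing.assert_allclose(tr.volume, expected, rtol=1e-6)

    def test_single_bolus_monoexponential_plasma(self, mouse_params):
        """One NP bolus, no tumor exchange: plasma mass is analytic."""
        p = mouse_params.replace(P_NP=1e-15)
        tr = simulate(p, bolus("antimir", 0.2), (0.0, 3.0),
                      initial=equilibrium_state(p, 0.1), t_eval_step=0.1,
                      rtol=1e-11)
        dose_mg = 0.2 * p.BW
        expected = dose_mg * np.exp(-(p.k_Cl + p.delta_NP) * tr.t)
        # step endpoints are integrated to rtol; interior samples come
        # from the solver's dense interpolant, which is slightly coarser
        assert tr["NP_plasma"][-1] == pytest.approx(expected[-1], rel=1e-8)
        np.testing.assert_allclose(tr["NP_plasma"], expected, rtol=1e-6)

    def test_np_mass_balance(self, mouse_params):
        """Injected = plasma + interstitium + cumulative sinks, to 1e-6."""
        reg = preclinical_twice_weekly("antimir", 0.2, 28.0)
        tr = simulate(mouse_params, reg, (0.0, 28.0),
                      initial=equilibrium_state(mouse_params, 0.1))
        injected = tr.injected_mass("antimir")
        total = tr["NP_plasma"] + tr["NP_interstitium"] + tr["NP_sink"]
        mask = injected > 0
        err = np.abs(total[mask] - injected[mask]) / injected[mask].max()
        assert err.max() < 1e-6

    def test_states_stay_non_negative(self, mouse_params):
        reg = Regimen({**preclinical_twice_weekly("antimir", 0.2, 28.0).doses,
                       "cisplatin": [(float(t), 8.0) for t in (0, 7, 14, 21)]})
        tr = simulate(mouse_params, reg, (0.0, 28.0),
                      initial=equilibrium_state(mouse_params, 0.1))
        assert tr.y.min() >= -1e-12

    def test_q3w_peak_intratumoral_drug_declines(self, human_params):
        """Tumor growth between Q3W doses dilutes each successive peak.

        The per-dose extravasated mass rises only ~V^(2/3) (vascular
        surface density falls as V^(-1/3)) while the interstitial
        distribution volume rises ~V, so the peak interstitial NP
        concentration — drug exposure per unit tumor — falls with every
        cycle as the tumor grows.
        """
        reg = build_regimen({"antimir": 0.026}, "Q3W", cycles=5)
        tr = simulate(human_params, reg, (0.0, 105.0),
                      initial=equilibrium_state(human_params, 1.77),
                      t_eval_step=0.05)
        conc = tr["NP_interstitium"] / (human_params.phi_int * tr.volume)
        peaks = []
        for t0 in (0.0, 21.0, 42.0, 63.0, 84.0):
            win = (tr.t >= t0) & (tr.t < t0 + 21.0)
            peaks.append(conc[win].max())
        assert all(b < a for a, b in zip(peaks, peaks[1:]))

    def test_end_volume_monotone_in_dose(self, human_params):
        """Higher anti-miR dose never yields a larger end-of-course tumor."""
        y0 = equilibrium_state(human_params, 1.77)
        vols = []
        for dose in (0.003, 0.03, 0.3, 3.0, 10.0):
            reg = build_regimen({"antimir": dose}, "Q3W")
            tr = simulate(human_params, reg, (0.0, 189.0), initial=y0,
                          rtol=1e-6, t_eval_step=3.0)
            vols.append(tr.volume[-1])
        assert all(b <= a * (1 + 1e-9) for a, b in zip(vols, vols[1:]))

    def test_solver_tolerance_convergence(self, mouse_params):
        """Halving rtol changes the end-of-treatment volume < 1e-4 relative."""
        reg = preclinical_twice_weekly("antimir", 0.2, 28.0)
        y0 = equilibrium_state(mouse_params, 0.1)
        v1 = simulate(mouse_params, reg, (0.0, 28.0), initial=y0,
                      rtol=1e-8).volume[-1]
        v2 = simulate(mouse_params, reg, (0.0, 28.0), initial=y0,
                      rtol=5e-9).volume[-1]
        assert abs(v1 - v2) / v1 < 1e-4

    def test_dose_outside_span_rejected(self, mouse_params):
        with pytest.raises(ValueError, match="t_span"):
            simulate(mouse_params, bolus("antimir", 0.2, day=50.0), (0.0, 28.0),
                     initial=equilibrium_state(mouse_params, 0.1))


class TestGrowToTreatmentStart:
    def test_target_equal_to_initial(self, mouse_params):
        state, t = grow_to_treatment_start(mouse_params, target_volume=0.1,
                                           initial_volume=0.1)
        assert t == 0.0
        assert state[IDX["V_tumor"]] == pytest.approx(0.1)

    def test_inverts_exponential_closed_form(self, growth_only_mouse,
                                             exp_growth_rate):
        v0, T = 0.01, 15.0
        target = v0 * np.exp(exp_growth_rate * T)
        _, t_hit = grow_to_treatment_start(growth_only_mouse,
                                           target_volume=target,
                                           initial_volume=v0)
        assert t_hit == pytest.approx(T, abs=0.01)

    def test_unreachable_target_rejected(self, mouse_params):
        # target above carrying capacity can never be reached
        with pytest.raises(ValueError):
            grow_to_treatment_start(mouse_params,
                                    target_volume=mouse_params.K * 2)

    def test_stalled_growth_rejects_patient(self, mouse_params):
        frozen = mouse_params.replace(gamma=1e-6)
        with pytest.raises(PatientRejected):
            grow_to_treatment_start(frozen, target_volume=1.0, cap_days=100.0)


class TestPercentInjectedDose:
    def test_plasma_100_percent_at_bolus(self, mouse_params):
        p = mouse_params.replace(P_NP=1e-15)
        tr = simulate(p, bolus("antimir", 0.2), (0.0, 2.0),
                      initial=equilibrium_state(p, 0.1), t_eval_step=0.25)
        pid = percent_injected_dose(tr, "NP_plasma")
        assert pid[0] == pytest.approx(100.0, rel=1e-9)
        assert np.nanmax(pid) <= 100.0 + 1e-9

    def test_undefined_before_first_dose(self, mouse_params):
        tr = simulate(mouse_params, bolus("antimir", 0.2, day=5.0), (0.0, 10.0),
                      initial=equilibrium_state(mouse_params, 0.1))
        pid = percent_injected_dose(tr, "NP_interstitium")
        assert np.all(np.isnan(pid[tr.t < 5.0]))
        assert np.all(np.isfinite(pid[tr.t >= 5.0]))

    def test_no_dose_raises(self, mouse_params):
        tr = simulate(mouse_params, None, (0.0, 5.0),
                      initial=equilibrium_state(mouse_params, 0.1))
        with pytest.raises(ValueError, match="no antimir dose"):
            percent_injected_dose(tr, "NP_plasma")

    def test_sink_matches_quadrature_oracle(self, mouse_params):
        """Cumulative sink equals the trapezoidal integral of loss rates."""
        p = mouse_params
        tr = simulate(p, bolus("antimir", 0.2), (0.0, 2.0),
                      initial=equilibrium_state(p, 0.1), t_eval_step=0.002)
        k_diff = p.D_NP * (100.0 / p.Phi_NP) / p.Len**2
        k_del = 1.0 / (1.0 / k_diff + 1.0 / p.k_up)
        rate = ((p.k_Cl + p.delta_NP) * tr["NP_plasma"]
                + (p.delta_NP + k_del) * tr["NP_interstitium"])
        from scipy.integrate import cumulative_trapezoid

        oracle = cumulative_trapezoid(rate, tr.t, initial=0.0)
        np.testing.assert_allclose(tr["NP_sink"], oracle, rtol=2e-4,
                                   atol=1e-9)
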