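"""Median-effect fits, combination index, and combination studies."""

import numpy as np
import pandas as pd
import pytest

from mirqsp.sampling import lhs_log_doses
from mirqsp.synergy import (
    MedianEffectFit,
    classify_ci,
    combination_index,
    median_effect_fit,
    run_combination_study,
    sample_dose_combinations,
)


def me_table(Dm, m, doses):
    doses = np.asarray(doses, float)
    return pd.DataFrame({"dose": doses, "fa": 1 / (1 + (Dm / doses) ** m)})


class TestMedianEffectFit:
    def test_two_point_log_logit_algebra(self):
        # fa 0.2 at 0.5 and 0.8 at 2 lie on the line m=2, Dm=1
        # (log-logit slope ln(16)/ln(4) = 2); a third consistent point
        # fa 0.5 at 1.0 keeps the fit requirements satisfied
        tab = pd.DataFrame({"dose": [0.5, 1.0, 2.0], "fa": [0.2, 0.5, 0.8]})
        fit = median_effect_fit(tab)
        assert fit.m == pytest.approx(2.0, rel=1e-10)
        assert fit.Dm == pytest.approx(1.0, rel=1e-10)

    def test_generative_identity(self):
        fit = median_effect_fit(me_table(1.0, 1.0, np.logspace(-1.5, 1.5, 9)))
        assert fit.Dm == pytest.approx(1.0, rel=1e-10)
        assert fit.m == pytest.approx(1.0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_half_effect_at_dm(self):
        fit = median_effect_fit(me_table(0.7, 1.8, np.logspace(-2, 1, 8)))
        assert fit.fa(fit.Dm) == pytest.approx(0.5, rel=1e-9)

    def test_extreme_fa_rows_dropped(self):
        tab = pd.DataFrame({"dose": [0.1, 0.5, 1.0, 2.0, 50.0],
                            "fa": [0.0, 0.2, 0.5, 0.8, 1.0]})
        fit = median_effect_fit(tab)
        assert fit.m == pytest.approx(2.0, rel=1e-9)

    def test_too_few_usable_rows_rejected(self):
        tab = pd.DataFrame({"dose": [0.5, 1.0, 2.0], "fa": [0.0, 0.5, 1.0]})
        with pytest.raises(ValueError, match="usable"):
            median_effect_fit(tab)


class TestCombinationIndex:
    FITS = {"a": MedianEffectFit(Dm=1.0, m=1.0, drug="a"),
            "b": MedianEffectFit(Dm=1.0, m=1.0, drug="b")}

    def test_single_drug_at_own_dx_is_one(self):
        fit = MedianEffectFit(Dm=0.5, m=1.7)
        dx = fit.dx(0.3)
        assert combination_index({"a": dx}, 0.3, {"a": fit}) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_loewe_additive_halves(self):
        # each drug at half its Dx for the observed effect: CI = 1
        ci = combination_index({"a": 0.5, "b": 0.5}, 0.5, self.FITS)
        assert ci == pytest.approx(1.0, abs=1e-12)

    def test_synergy_worksheet(self):
        # Dm=1, m=1 both; combo (0.2, 0.2) with observed fa 0.5:
        # Dx = 1 each, CI = 0.2/1 + 0.2/1 = 0.4
        ci = combination_index({"a": 0.2, "b": 0.2}, 0.5, self.FITS)
        assert ci == pytest.approx(0.4, abs=1e-10)

    def test_hand_computed_three_drug_worksheet(self):
        fits = {
            "a": MedianEffectFit(Dm=2.0, m=1.0),
            "b": MedianEffectFit(Dm=0.5, m=2.0),
            "c": MedianEffectFit(Dm=1.0, m=0.5),
        }
        fa = 0.8  # fa/(1-fa) = 4
        # Dx_a = 2*4 = 8; Dx_b = 0.5*4^(1/2) = 1; Dx_c = 1*4^2 = 16
        ci = combination_index({"a": 2.0, "b": 0.25, "c": 4.0}, fa, fits)
        assert ci == pytest.approx(2 / 8 + 0.25 / 1 + 4 / 16, abs=1e-10)

    def test_zero_dose_drug_drops_out(self):
        fit = MedianEffectFit(Dm=1.0, m=1.0)
        ci = combination_index({"a": 0.0, "b": fit.dx(0.4)}, 0.4,
                               {"a": fit, "b": fit})
        assert ci == pytest.approx(1.0, abs=1e-12)

    def test_scale_consistency(self):
        ci1 = combination_index({"a": 0.3, "b": 0.1}, 0.6, self.FITS)
        ci2 = combination_index({"a": 0.6, "b": 0.2}, 0.6, self.FITS)
        assert ci2 == pytest.approx(2 * ci1, rel=1e-12)

    def test_degenerate_fa_rejected(self):
        for bad in (0.0, 1.0, -0.2, 1.4):
            with pytest.raises(ValueError):
                combination_index({"a": 1.0}, bad, self.FITS)

    def test_classification_thresholds(self):
        assert classify_ci(0.299) == "strong synergy"
        assert classify_ci(0.3) == "synergy"
        assert classify_ci(0.899) == "synergy"
        assert classify_ci(0.9) == "additive"
        assert classify_ci(1.1) == "additive"
        assert classify_ci(1.100001) == "antagonism"


class TestDoseSampling:
    BOUNDS = {"antimir": (0.01, 2.5), "cisplatin": (0.01, 2.04)}

    def test_within_bounds(self):
        s = sample_dose_combinations(self.BOUNDS, n=50, seed=0)
        for drug, (lo, hi) in self.BOUNDS.items():
            assert s[drug].between(lo, hi).all()

    def test_log_marginal_stratification(self):
        n = 50
        s = sample_dose_combinations(self.BOUNDS, n=n, seed=1)
        for drug, (lo, hi) in self.BOUNDS.items():
            u = (np.log(s[drug]) - np.log(lo)) / (np.log(hi) - np.log(lo))
            assert np.all(np.histogram(u, bins=n, range=(0, 1))[0] == 1)

    def test_seed_determinism(self):
        a = sample_dose_combinations(self.BOUNDS, 20, seed=5)
        b = sample_dose_combinations(self.BOUNDS, 20, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            lhs_log_doses({"a": (0.0, 1.0)}, 5, 0)


class TestCombinationStudy:
    def _independent_targets_fa(self, fits):
        """Bliss-independent two-target testbed: fa = 1-(1-fa_a)(1-fa_b).

        Each drug saturates its own target; joint action on independent
        targets yields CI < 1 over most of the dose space.
        """

        def fa_fn(regimen):
            fa = {d: fits[d].fa(ev[0][1]) for d, ev in regimen.doses.items()}
            out = 1.0
            for v in fa.values():
                out *= 1.0 - v
            return float(np.clip(1.0 - out, 0.01, 0.99))

        return fa_fn

    def test_independent_targets_mostly_synergistic(self):
        fits = {"a": MedianEffectFit(Dm=0.5, m=1.2, drug="a"),
                "b": MedianEffectFit(Dm=0.8, m=1.0, drug="b")}
        res = run_combination_study(
            self._independent_targets_fa(fits),
            {"a": (0.01, 2.5), "b": (0.01, 2.0)},
            fits, n=50, seed=2,
        )
        valid = res["ci"].dropna()
        assert len(valid) == 50
        assert (valid < 1.0).mean() > 0.5
        frac = res.attrs["fraction_synergistic"]
        assert frac == pytest.approx((valid < 0.9).sum() / 50)

    def test_failures_logged_not_fatal(self):
        fits = {"a": MedianEffectFit(Dm=1.0, m=1.0, drug="a")}

        def flaky(regimen):
            dose = regimen.doses["a"][0][1]
            if dose > 1.0:
                raise RuntimeError("solver blew up")
            return 0.5

        res = run_combination_study(flaky, {"a": (0.01, 2.5)}, fits,
                                    n=20, seed=0)
        assert res["ci"].isna().sum() > 0
        assert res["ci"].notna().sum() > 0
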