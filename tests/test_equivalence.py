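"""Calibration curves, marker quantification and the equivalence 90% CI."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hecm.equivalence import (
    CalibrationCurve,
    ToxicityGroup,
    equivalence_ci,
    equivalence_decision,
    fit_calibration,
    hecm_dose,
    quantify,
)
from hecm.synthetic import calibration_points, generate_equivalence_groups

from hecm.datasets import reference_calibration

# Published calibration parameters of the two diterpenoid-lactone markers.
_CAL = reference_calibration().set_index("analyte")


def _params(analyte):
    r = _CAL.loc[analyte]
    return dict(slope=r["slope"], intercept=r["intercept"],
                rng=(r["range_low_ug_ml"], r["range_high_ug_ml"]), r2=r["r2"])


DIOB = _params("DIOB")
EEA = _params("EEA")


class TestFitCalibration:
    def test_exact_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2 * xi + 1 for xi in x]
        c = fit_calibration(x, y)
        assert c.slope == pytest.approx(2.0)
        assert c.intercept == pytest.approx(1.0)
        assert c.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("params", [DIOB, EEA], ids=["DIOB", "EEA"])
    def test_synthetic_standards_recover_printed_curves(self, params):
        x, y = calibration_points(
            params["slope"], params["intercept"], params["r2"], params["rng"]
        )
        c = fit_calibration(x, y)
        assert c.slope == pytest.approx(params["slope"], rel=1e-9)
        assert c.intercept == pytest.approx(params["intercept"], rel=1e-6)
        assert round(c.r2, 4) == params["r2"]

    def test_lod_loq_from_residual_sd(self, rng):
        x = np.linspace(1, 10, 8)
        noise = rng.normal(0, 0.5, size=8)
        y = 3.0 * x + 2.0 + noise
        c = fit_calibration(x, y)
        res = stats.linregress(x, y)
        resid = y - (res.slope * x + res.intercept)
        sigma = math.sqrt((resid**2).sum() / 6)
        assert c.lod == pytest.approx(3.3 * sigma / res.slope)
        assert c.loq == pytest.approx(10 * sigma / res.slope)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_calibration([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestQuantify:
    def _curve(self):
        return CalibrationCurve(
            slope=2.0, intercept=1.0, range=(1.0, 100.0), r2=0.999, lod=0.5, loq=1.5
        )

    def test_response_at_intercept_is_zero_and_below_lod(self):
        q = quantify(1.0, self._curve())
        assert q.conc == pytest.approx(0.0)
        assert q.below_lod and q.below_loq and q.outside_range

    def test_inverse_identity(self):
        c = self._curve()
        q = quantify(2.0 * 50 + 1.0, c)
        assert q.conc == pytest.approx(50.0)
        assert not q.below_loq and not q.outside_range

    def test_roundtrip_over_test_range(self):
        x, y = calibration_points(**{
            "slope": DIOB["slope"], "intercept": DIOB["intercept"],
            "r2": DIOB["r2"], "conc_range": DIOB["rng"],
        })
        c = fit_calibration(x, y)
        for conc in np.linspace(*DIOB["rng"], 7):
            assert quantify(c.predict(conc), c).conc == pytest.approx(conc, abs=1e-9)


class TestHecmDose:
    def test_boundaries_and_product(self):
        assert hecm_dose(0.0, 2000.0) == 0.0
        assert hecm_dose(1.0, 1234.0) == 1234.0
        # 6.6% content of a 2 g/kg extract dose
        assert hecm_dose(0.066, 2000.0) == pytest.approx(132.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hecm_dose(1.2, 100.0)
        with pytest.raises(ValueError):
            hecm_dose(0.5, 0.0)


class TestEquivalenceCI:
    def test_identical_groups_degenerate_ci(self):
        g = ToxicityGroup("a", [100.0, 100.0, 100.0])
        r = equivalence_ci(g, ToxicityGroup("b", [100.0, 100.0, 100.0]))
        assert r.ratio_ci == pytest.approx((1.0, 1.0))
        assert r.equivalent

    def test_hand_computed_interval(self):
        # n1 = n2 = 5, log-mean difference 0.1, sigma_w = 0.2:
        # t(0.95, 8) = 1.85955, half-width = 1.85955 * 0.2 * sqrt(0.2)
        # = 0.166325 -> CI = (e^-0.066325, e^0.266325)
        rng = np.random.default_rng(0)
        base = rng.normal(0.0, 1.0, 5)
        base -= base.mean()
        base /= base.std(ddof=1)  # exact mean 0, sd 1
        logs_b = 5.0 + 0.1 + 0.2 * base
        logs_h = 5.0 + 0.2 * base
        r = equivalence_ci(
            ToxicityGroup("cand", np.exp(logs_b)), ToxicityGroup("orig", np.exp(logs_h))
        )
        assert r.sigma_w == pytest.approx(0.2)
        assert r.t_quantile == pytest.approx(1.85955, abs=1e-4)
        assert r.ratio_ci[0] == pytest.approx(0.9358, abs=5e-5)
        assert r.ratio_ci[1] == pytest.approx(1.3052, abs=5e-5)
        assert r.equivalent

    def test_ratio_two_not_equivalent(self):
        cand, orig = generate_equivalence_groups(2.0, 0.05, 8, seed=1)
        r = equivalence_ci(cand, orig)
        assert r.ratio_ci[0] > 1.43
        assert not r.equivalent

    def test_midpoint_is_geometric_mean_ratio(self, rng):
        cand = ToxicityGroup("c", rng.lognormal(8.0, 0.3, 10))
        orig = ToxicityGroup("o", rng.lognormal(8.1, 0.3, 10))
        r = equivalence_ci(cand, orig)
        gm_ratio = np.exp(np.log(cand.values).mean() - np.log(orig.values).mean())
        assert math.sqrt(r.ratio_ci[0] * r.ratio_ci[1]) == pytest.approx(gm_ratio)

    def test_swap_maps_ci_to_reversed_reciprocal(self, rng):
        cand = ToxicityGroup("c", rng.lognormal(8.0, 0.3, 10))
        orig = ToxicityGroup("o", rng.lognormal(8.2, 0.4, 12))
        r1 = equivalence_ci(cand, orig)
        r2 = equivalence_ci(orig, cand)
        assert r2.ratio_ci[0] == pytest.approx(1.0 / r1.ratio_ci[1])
        assert r2.ratio_ci[1] == pytest.approx(1.0 / r1.ratio_ci[0])

    def test_width_monotone_in_sigma_and_n(self):
        def width(sd, n):
            base = np.array([-1.0, -0.5, 0.0, 0.5, 1.0] * (n // 5))[:n]
            base = (base - base.mean()) / base.std(ddof=1)
            vals = np.exp(5.0 + sd * base)
            r = equivalence_ci(ToxicityGroup("a", vals), ToxicityGroup("b", vals))
            return math.log(r.ratio_ci[1]) - math.log(r.ratio_ci[0])

        widths_sd = [width(sd, 10) for sd in (0.1, 0.2, 0.4, 0.8)]
        assert all(a < b for a, b in zip(widths_sd, widths_sd[1:]))
        widths_n = [width(0.3, n) for n in (5, 10, 20, 40)]
        assert all(a > b for a, b in zip(widths_n, widths_n[1:]))

    def test_textbook_se_is_wider_by_sqrt2_on_log_scale(self, rng):
        cand = ToxicityGroup("c", rng.lognormal(8.0, 0.3, 10))
        orig = ToxicityGroup("o", rng.lognormal(8.0, 0.3, 10))
        r = equivalence_ci(cand, orig)
        rt = equivalence_ci(cand, orig, textbook_se=True)
        w = math.log(r.ratio_ci[1] / r.ratio_ci[0])
        wt = math.log(rt.ratio_ci[1] / rt.ratio_ci[0])
        assert wt == pytest.approx(w * math.sqrt(2.0))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            ToxicityGroup("a", [10.0, -1.0])

    def test_anova_pooling_with_extra_groups(self, rng):
        groups = [ToxicityGroup(f"g{i}", rng.lognormal(8, 0.3, 6)) for i in range(4)]
        r = equivalence_ci(groups[0], groups[1], extra_groups=groups[2:])
        logs = [np.log(g.values) for g in groups]
        ss = sum(((lg - lg.mean()) ** 2).sum() for lg in logs)
        assert r.sigma_w == pytest.approx(math.sqrt(ss / (4 * 5)))


class TestEquivalenceDecision:
    def _result(self, lo, hi):
        g = ToxicityGroup("x", [1.0, 2.0])
        r = equivalence_ci(g, g)
        r.ratio_ci = (lo, hi)
        return r

    def test_printed_s22_alt_interval_passes(self):
        ok, text = equivalence_decision(self._result(0.999, 1.256))
        assert ok
        assert "99.9-125.6%" in text

    def test_interval_outside_limits_fails(self):
        ok, _ = equivalence_decision(self._result(0.65, 1.20))
        assert not ok

    def test_boundary_is_open(self):
        ok, _ = equivalence_decision(self._result(0.70, 1.43))
        assert not ok
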