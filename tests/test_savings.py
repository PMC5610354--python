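"""Annualised rate curves, intersections, area-based savings and ROI."""

import numpy as np
import pytest
from scipy import integrate

from bacikit.regression import fit_segment
from bacikit.savings import (
    AnnualRateCurve,
    annualize,
    estimate_savings,
    find_intersection,
    rate_reduction,
    roi,
)
from tests.conftest import make_series

YEAR = 365.0


def curve(a, b, width=30, transform="sqrt", unit="AUD"):
    return AnnualRateCurve(bin_width=width, a=a, b=b, domain=(-36.0, 12.0),
                           transform=transform, unit=unit)


def numeric_total(c, t0, t1):
    """Quadrature oracle: integrate the rate over days, in years."""
    val, _ = integrate.quad(lambda d: float(c.rate(d / c.bin_width)), t0 * c.bin_width,
                            t1 * c.bin_width, limit=200)
    return val / YEAR


class TestAnnualize:
    def test_constant_sqrt_fit_closed_form(self):
        c = curve(10.0, 0.0)
        assert c.rate(0) == pytest.approx(100 * 365 / 30)
        assert c.rate(7.3) == pytest.approx(100 * 365 / 30)

    def test_zero_fit_gives_zero_curve(self):
        c = curve(0.0, 0.0)
        assert float(c.rate(3.0)) == 0.0

    def test_pointwise_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(10, 2), rng.normal(0, 0.3)
        c = curve(a, b)
        ts = np.linspace(-10, 12, 100)
        np.testing.assert_allclose(c.rate(ts), (a + b * ts) ** 2 * 365 / 30, rtol=1e-12)

    def test_from_segment_fit(self):
        s = make_series([3.0, 4.0, 5.0], bins=[0, 1, 2], transform="sqrt")
        f = fit_segment(s, "after")
        c = annualize(f, 30)
        assert c.a == pytest.approx(3.0) and c.b == pytest.approx(1.0)

    def test_identity_curve_clips_at_zero(self):
        c = curve(1.0, -1.0, transform="identity")
        assert float(c.rate(5.0)) == 0.0


class TestIntersection:
    def test_identical_curves_meet_at_day_zero(self):
        assert find_intersection(curve(10, 1), curve(10, 1)) == 0.0

    def test_hand_solvable_crossing(self):
        # 10 + t = 11 + 0*t  ->  t* = 1 bin = 30 days
        assert find_intersection(curve(10, 1), curve(11, 0)) == pytest.approx(30.0)

    def test_parallel_distinct_curves_never_cross(self):
        assert find_intersection(curve(10, 1), curve(11, 1)) is None

    def test_crossing_outside_year_reported_absent(self):
        # t* = 20 bins = 600 days > 365
        assert find_intersection(curve(10, 0.1), curve(12, 0.0)) is None

    @pytest.mark.parametrize("seed", range(8))
    def test_root_agrees_with_bisection_on_squared_curves(self, seed):
        rng = np.random.default_rng(seed)
        before = curve(rng.uniform(5, 15), rng.uniform(0.1, 0.5))
        after = curve(before.a + rng.uniform(0.1, 2.0), before.b - rng.uniform(0.2, 0.6))
        day = find_intersection(before, after)
        if day is None:
            return
        f = lambda d: float(before.rate(d / 30) - after.rate(d / 30))
        lo, hi = max(0.0, day - 20), day + 20
        if f(lo) * f(hi) > 0:
            return  # double root at tangency; sign test inapplicable
        for _ in range(80):  # bisection oracle
            mid = (lo + hi) / 2
            if f(lo) * f(mid) <= 0:
                hi = mid
            else:
                lo = mid
        assert day == pytest.approx((lo + hi) / 2, abs=1e-6)


class TestSavings:
    def test_identical_curves_save_nothing(self):
        est = estimate_savings(curve(10, 0.2), curve(10, 0.2))
        assert est.saving == 0.0 and est.saving_pct == 0.0
        assert est.rate_reduction_pct == 0.0

    def test_constant_rate_rectangles(self):
        w = 30
        a_before = np.sqrt(1000 * w / YEAR)
        a_after = np.sqrt(500 * w / YEAR)
        est = estimate_savings(curve(a_before, 0.0, w), curve(a_after, 0.0, w),
                               start_day=0.0)
        assert est.projected_annual_total == pytest.approx(1000.0)
        assert est.actual_annual_total == pytest.approx(500.0)
        assert est.saving == pytest.approx(500.0)
        assert est.saving_pct == pytest.approx(50.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_closed_form_area_matches_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        before = curve(rng.uniform(8, 15), rng.uniform(0.0, 0.4))
        after = curve(rng.uniform(8, 15), rng.uniform(-0.1, 0.4))
        est = estimate_savings(before, after, start_day=0.0)
        assert est.projected_annual_total == pytest.approx(
            numeric_total(before, 0, YEAR / 30), rel=1e-8
        )
        assert est.actual_annual_total == pytest.approx(
            numeric_total(after, 0, YEAR / 30), rel=1e-8
        )

    def test_saving_antisymmetric_under_swap(self):
        b, a = curve(12, 0.3), curve(12, 0.1)
        assert estimate_savings(b, a).saving == pytest.approx(
            -estimate_savings(a, b).saving, abs=1e-9
        )

    def test_worse_after_curve_reports_negative_saving(self):
        est = estimate_savings(curve(10, 0.0), curve(12, 0.0), start_day=0.0)
        assert est.saving < 0

    def test_identity_scale_clipped_integration_matches_quadrature(self):
        before = curve(40.0, -5.0, transform="identity")  # crosses zero mid-year
        after = curve(10.0, 0.0, transform="identity")
        est = estimate_savings(before, after, start_day=0.0)
        assert est.projected_annual_total == pytest.approx(
            numeric_total(before, 0, YEAR / 30), rel=1e-6
        )

    def test_sign_change_extrapolation_refused(self):
        # after-line hits zero inside the year: (a+bt) flips sign
        with pytest.raises(ValueError, match="sign"):
            estimate_savings(curve(10, 0.1), curve(5, -1.0), start_day=0.0)

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            estimate_savings(curve(10, 0.1, unit="AUD"), curve(10, 0.1, unit="days"))


class TestRateReductionAndROI:
    def test_equal_curves_zero_reduction(self):
        assert rate_reduction(curve(10, 0.2), curve(10, 0.2)) == 0.0

    def test_half_rate_is_fifty_percent(self):
        after_a = curve(10, 0.0).a / np.sqrt(2)
        assert rate_reduction(curve(10, 0.0), curve(after_a, 0.0)) == pytest.approx(50.0)

    def test_zero_before_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_reduction(curve(0, 0.0), curve(1, 0.0))

    def test_roi_worked_example(self):
        assert roi(19000, 2760) == pytest.approx(6.88, abs=0.005)
        assert roi(0, 100) == 0.0
        assert roi(100, 100) == 1.0
        with pytest.raises(ValueError):
            roi(100, 0)
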