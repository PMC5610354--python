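"""Segment fits, ANCOVA slope comparison, prediction intervals, outliers."""

import numpy as np
import pytest

from bacikit.regression import (
    compare_slopes,
    exclude_outliers,
    fit_segment,
    prediction_interval,
)
from tests.conftest import make_series


def normal_equations(x, y):
    """Independent closed-form OLS oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    return y.mean() - slope * x.mean(), slope


class TestFitSegment:
    def test_exact_line(self):
        s = make_series([1.0, 2.0, 3.0], bins=[0, 1, 2])
        f = fit_segment(s, "after")
        assert f.slope == pytest.approx(1.0, abs=1e-12)
        assert f.intercept == pytest.approx(1.0, abs=1e-12)
        assert f.r2 == pytest.approx(1.0) and f.sse == pytest.approx(0.0, abs=1e-20)

    def test_constant_series_has_zero_slope_and_r2(self):
        f = fit_segment(make_series([4.0] * 10, bins=range(10)), "after")
        assert f.slope == pytest.approx(0.0, abs=1e-12)
        assert f.r2 == 0.0 and f.adj_r2 <= f.r2

    @pytest.mark.parametrize("seed", range(5))
    def test_coefficients_match_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 11)
        x = np.sort(rng.choice(np.arange(-36, 0), n, replace=False))
        y = rng.normal(5, 2, n)
        f = fit_segment(make_series(y, bins=x), "before", outlier_exclusion=False)
        a, b = normal_equations(x, y)
        assert f.intercept == pytest.approx(a, abs=1e-10)
        assert f.slope == pytest.approx(b, abs=1e-10)
        assert f.rmse == pytest.approx(np.sqrt(f.sse / (n - 2)), abs=1e-12)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_segment(make_series([1.0, 2.0], bins=[0, 1]), "after")


class TestCompareSlopes:
    def test_noiseless_halved_slope(self):
        bins = np.arange(-36, 12)
        b1 = 0.4
        y = 10 + b1 * bins - 0.5 * b1 * bins * (bins >= 0)
        cmp = compare_slopes(make_series(y, bins))
        assert cmp.interaction_estimate == pytest.approx(-0.5 * b1, abs=1e-9)
        assert cmp.p_interaction < 1e-6
        assert cmp.interaction_estimate == pytest.approx(
            cmp.fit_after.slope - cmp.fit_before.slope, abs=1e-9
        )

    def test_interaction_t_equals_partial_f(self):
        rng = np.random.default_rng(3)
        bins = np.arange(-36, 12)
        for _ in range(20):
            y = 5 + 0.2 * bins + rng.normal(0, 1, bins.size)
            cmp = compare_slopes(make_series(y, bins), outlier_exclusion=False)
            assert cmp.p_interaction == pytest.approx(cmp.p_partial_f, abs=1e-10)

    def test_continuing_line_gives_nonsignificant_common_contrast(self):
        """When the after data continue the before line, pooling does not
        move the slope (the Fig-2D-style check)."""
        rng = np.random.default_rng(8)
        bins = np.arange(-36, 12)
        y = 5 + 0.2 * bins + rng.normal(0, 0.3, bins.size)
        cmp = compare_slopes(make_series(y, bins))
        assert cmp.p_common_vs_before > 0.2

    def test_difference_interaction_decomposes_on_noiseless_input(self):
        bins = np.arange(-36, 12)
        after = bins >= 0
        test_y = 10 + 0.3 * bins - 0.2 * bins * after
        ctrl_y = 11 + 0.25 * bins + 0.05 * bins * after
        diff = ctrl_y - test_y
        i_t = compare_slopes(make_series(test_y, bins)).interaction_estimate
        i_c = compare_slopes(make_series(ctrl_y, bins)).interaction_estimate
        i_d = compare_slopes(make_series(diff, bins)).interaction_estimate
        assert i_d == pytest.approx(i_c - i_t, abs=1e-9)

    def test_insufficient_period_rejected(self):
        with pytest.raises(ValueError):
            compare_slopes(make_series(np.arange(5, dtype=float), bins=[-2, -1, 0, 1, 2]))


class TestPredictionInterval:
    def test_zero_residual_fit_has_zero_width(self):
        f = fit_segment(make_series([1.0, 2.0, 3.0, 4.0], bins=[0, 1, 2, 3]), "after")
        lo, hi = prediction_interval(f, 2.0)
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_width_grows_away_from_centroid(self):
        rng = np.random.default_rng(4)
        x = np.arange(-36, 0)
        f = fit_segment(make_series(5 + 0.1 * x + rng.normal(0, 1, x.size), x), "before")
        w = lambda t: np.subtract(*reversed(prediction_interval(f, t)))
        centre = x.mean()
        assert w(centre + 30) > w(centre)
        assert w(centre - 30) > w(centre)

    def test_symmetry_about_fitted_value(self):
        rng = np.random.default_rng(5)
        x = np.arange(-10, 0)
        f = fit_segment(make_series(rng.normal(0, 1, 10), x), "before")
        lo, hi = prediction_interval(f, -3.0)
        assert (lo + hi) / 2 == pytest.approx(f.predict(-3.0), abs=1e-10)

    def test_invalid_level_rejected(self):
        f = fit_segment(make_series([1.0, 2.0, 3.0], bins=[0, 1, 2]), "after")
        with pytest.raises(ValueError):
            prediction_interval(f, 0.0, level=1.5)


class TestOutlierExclusion:
    def test_clean_linear_data_untouched(self):
        rng = np.random.default_rng(5)
        bins = np.arange(-30, 0)
        s = make_series(5 + 0.1 * bins + rng.normal(0, 0.5, 30), bins)
        _, removed = exclude_outliers(s, "before")
        assert removed == []

    def test_planted_gross_outlier_is_the_one_removed(self):
        rng = np.random.default_rng(7)
        bins = np.arange(-30, 0)
        y = 5 + 0.1 * bins + rng.normal(0, 0.5, 30)
        y[12] += 10 * 0.5  # displace one bin by 10 sigma
        _, removed = exclude_outliers(make_series(y, bins), "before")
        assert removed == [int(bins[12])]

    def test_identical_values_nothing_removed(self):
        s = make_series([3.0] * 20, bins=np.arange(-20, 0))
        _, removed = exclude_outliers(s, "before")
        assert removed == []

    def test_removal_capped_at_ten_percent(self):
        rng = np.random.default_rng(9)
        bins = np.arange(-30, 0)
        y = 5 + 0.1 * bins + rng.normal(0, 0.2, 30)
        # staggered gross outliers, one more than the cap allows
        y[[2, 9, 16, 23]] += np.array([40.0, 80.0, 120.0, 160.0])
        _, removed = exclude_outliers(make_series(y, bins), "before")
        assert len(removed) == 3  # floor(0.1 * 30)
        assert set(removed) <= {-28, -21, -14, -7}
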