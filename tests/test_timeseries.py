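"""Binning conventions, cross-patient averaging and transform choice."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bacikit.timeseries import (
    BIN_RANGES,
    average_patients,
    apply_transform,
    bin_patients,
    difference_series,
    select_transform,
)
from tests.conftest import make_series


def one_patient(death_day=np.nan):
    return pd.DataFrame(
        {"patient_id": ["p1"], "arm": ["test"], "death_day": [death_day]}
    )


def claims(days, costs, pid="p1"):
    return pd.DataFrame({"patient_id": pid, "day": days, "cost": costs})


class TestBinning:
    @pytest.mark.parametrize(
        "day,expected_bin",
        [(-1, -1), (0, 0), (-30, -1), (-31, -2), (29, 0), (30, 1), (-1080, -36)],
    )
    def test_half_open_boundary_convention(self, day, expected_bin):
        totals, _ = bin_patients(claims([day], [5.0]), one_patient(), 30)
        assert totals.loc["p1", expected_bin] == 5.0
        assert totals.loc["p1"].sum() == 5.0  # lands in exactly one bin

    def test_uniform_one_dollar_per_day_gives_30_per_before_bin(self):
        days = np.arange(-1080, 0)
        totals, _ = bin_patients(claims(days, np.ones(days.size)), one_patient(), 30)
        before = totals.loc["p1", totals.columns < 0]
        assert (before == 30.0).all()

    def test_bin_counts_per_width(self):
        assert BIN_RANGES[30] == (-36, 12) and 12 - (-36) == 48
        assert BIN_RANGES[100] == (-11, 4) and 4 - (-11) == 15

    def test_death_truncated_bins_are_unobserved_not_zero(self):
        # death on day 10: bin 0 (days 0..29) is cut short
        totals, log = bin_patients(claims([5, -5], [7.0, 9.0]), one_patient(10.0), 30)
        assert np.isnan(totals.loc["p1", 0])
        assert np.isnan(totals.loc["p1", 1])
        assert totals.loc["p1", -1] == 9.0  # fully observed pre-death bin
        assert log.total_truncated == 7.0  # the day-5 event fell in a truncated bin

    def test_out_of_range_events_logged_not_binned(self):
        totals, log = bin_patients(claims([400, -2000], [3.0, 4.0]), one_patient(), 30)
        assert log.n_out_of_range == 2
        assert log.total_out_of_range == 7.0
        assert totals.loc["p1"].fillna(0).sum() == 0.0

    @given(
        days=st.lists(st.integers(min_value=-1200, max_value=450), min_size=1, max_size=60),
        seed=st.integers(0, 10),
    )
    def test_conservation_of_total_cost(self, days, seed):
        """Observed bin totals plus discards equal the raw event total."""
        rng = np.random.default_rng(seed)
        costs = rng.gamma(2.0, 50.0, len(days))
        death = float(rng.integers(0, 360)) if rng.random() < 0.5 else np.nan
        ev = claims(days, costs)
        if not np.isnan(death):
            ev = ev[ev["day"] <= death].reset_index(drop=True)
        totals, log = bin_patients(ev, one_patient(death), 30)
        binned = np.nansum(totals.to_numpy())
        assert binned + log.discarded_total == pytest.approx(ev["cost"].sum(), rel=1e-12)


class TestAveraging:
    def test_single_patient_mean_is_identity(self):
        totals = pd.DataFrame([[1.0, 2.0, 3.0]], index=["a"], columns=[-2, -1, 0])
        s = average_patients(totals, "medical_cost", 30)
        assert s.values.tolist() == [1.0, 2.0, 3.0]

    def test_mean_and_observed_count(self):
        totals = pd.DataFrame(
            [[10.0, np.nan], [20.0, 4.0]], index=["a", "b"], columns=[-1, 0]
        )
        s = average_patients(totals, "medical_cost", 30)
        assert s.values[-1] == 15.0
        assert s.values[0] == 4.0
        assert s.n_observed.tolist() == [2, 1]

    def test_matches_elementwise_oracle_on_random_cohort(self):
        rng = np.random.default_rng(5)
        arr = rng.gamma(2, 10, size=(20, 48))
        arr[rng.random(arr.shape) < 0.1] = np.nan
        totals = pd.DataFrame(arr, index=[f"p{i}" for i in range(20)],
                              columns=np.arange(-36, 12))
        s = average_patients(totals, "medical_cost", 30)
        np.testing.assert_allclose(s.values.to_numpy(), np.nanmean(arr, axis=0))


class TestTransformSelection:
    def test_perfect_line_keeps_identity(self):
        bins = np.arange(-36, 12)
        s = make_series(10 + 0.5 * (bins + 36), bins)
        assert select_transform(s)[0] == "identity"

    def test_square_of_noisy_line_selects_sqrt(self):
        """The generating transform is the oracle: sqrt linearises it."""
        bins = np.arange(-36, 12)
        rng = np.random.default_rng(0)
        y = (5 + 0.8 * (bins + 36) + rng.normal(0, 0.5, bins.size)) ** 2
        chosen, report = select_transform(make_series(y, bins))
        assert chosen == "sqrt"
        assert report["identity"] < 0.05 <= report["sqrt"]

    def test_zero_bin_excludes_log(self):
        bins = np.arange(-36, 12)
        y = (10 + 0.5 * (bins + 36)).astype(float)
        y[0] = 0.0
        _, report = select_transform(make_series(y, bins))
        assert "log" not in report

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            select_transform(make_series([1, 2, 3, 4, 5]))


class TestTransformsAndDifferences:
    def test_sqrt_requires_nonnegative(self):
        with pytest.raises(ValueError):
            apply_transform(make_series([-1.0] * 10), "sqrt")

    def test_identical_series_difference_is_zero(self):
        s = make_series(np.arange(48, dtype=float))
        d = difference_series(s, s)
        assert (d.values == 0).all()

    def test_constant_shift(self):
        t = make_series(np.arange(48, dtype=float))
        c = make_series(np.arange(48, dtype=float) + 5)
        assert (difference_series(c, t).values == 5).all()

    def test_random_pair_matches_elementwise_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=48), rng.normal(size=48)
        d = difference_series(make_series(a), make_series(b))
        np.testing.assert_allclose(d.values.to_numpy(), a - b)

    def test_transform_scale_mismatch_rejected(self):
        t = make_series(np.arange(48, dtype=float) + 1)
        c = apply_transform(t, "sqrt")
        with pytest.raises(ValueError):
            difference_series(c, t)
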