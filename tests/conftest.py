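import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bacikit.timeseries import BinnedSeries

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_series(values, bins=None, width=30, transform="identity", label="medical_cost"):
    """Build a BinnedSeries from raw values (default bins -36..11)."""
    values = np.asarray(values, dtype=float)
    if bins is None:
        bins = np.arange(-36, -36 + values.size)
    index = pd.Index(np.asarray(bins, dtype=int))
    return BinnedSeries(
        bin_width=width,
        values=pd.Series(values, index=index),
        n_observed=pd.Series(np.where(np.isnan(values), 0, 1).astype(int), index=index),
        transform=transform,
        outcome_label=label,
    )


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def patients_frame():
    """Small hand-built patient table for matching tests."""

    def build(rows):
        cols = ["patient_id", "arm", "age_at_intervention", "gender",
                "diagnosis_group", "seifa"]
        df = pd.DataFrame(rows, columns=cols)
        df["death_day"] = np.nan
        df["intervention_date"] = 0
        df["matched_test_id"] = ""
        return df

    return build
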