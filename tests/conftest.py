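import datetime as dt

import numpy as np
import pandas as pd
import pytest


def make_daily(start, means, maxs=None, mins=None, valid=None, n_obs=24):
    """Build a daily-summary frame from per-day mean temperatures."""
    start = pd.Timestamp(start).date()
    dates = [start + dt.timedelta(days=i) for i in range(len(means))]
    means = np.asarray(means, dtype=float)
    maxs = means + 0.5 if maxs is None else np.asarray(maxs, dtype=float)
    mins = means - 0.5 if mins is None else np.asarray(mins, dtype=float)
    valid = np.ones(len(means), bool) if valid is None else np.asarray(valid, bool)
    return pd.DataFrame(
        {
            "mean_temp": means,
            "max_temp": maxs,
            "min_temp": mins,
            "dtr": maxs - mins,
            "n_obs": n_obs,
            "valid": valid,
        },
        index=pd.Index(dates, name="date"),
    )


def simulate_ordinal(rng, X, cutpoints, beta):
    """Draw ordinal responses from the proportional-odds model."""
    eta = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    cum = 1.0 / (1.0 + np.exp(-(np.asarray(cutpoints)[None, :] - eta[:, None])))
    u = rng.uniform(size=len(eta))
    return (u[:, None] > cum).sum(axis=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hourly_series():
    """One constant-ish day of hourly readings."""
    from reefstress.temperature import TemperatureSeries

    idx = pd.date_range("2016-07-01", periods=48, freq="h")
    temps = np.where(np.arange(48) % 2 == 0, 29.0, 31.0)
    return TemperatureSeries(site="test", data=pd.Series(temps.astype(float), index=idx))
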