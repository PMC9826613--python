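import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reefstress.errors import InsufficientDataError
from reefstress.indices import (
    ThermalConfig,
    compute_acute,
    compute_csa,
    compute_dhd,
    compute_dhm,
    compute_heating_rate1,
    compute_max3d,
    compute_mdhw,
    compute_mmm_max,
    dtr_stats,
    hotspots,
    thermal_report,
)

from conftest import make_daily

CFG = ThermalConfig(mmm_max=29.9)


def hs_series(values, start="2016-07-01"):
    daily = make_daily(start, 29.9 + np.asarray(values, dtype=float))
    return hotspots(daily, CFG)


class TestMmmMax:
    def test_constant_months(self):
        daily = {
            2016: make_daily("2016-07-01", np.full(62, 30.0)),
            2017: make_daily("2017-07-01", np.full(62, 30.0)),
        }
        assert compute_mmm_max(daily) == pytest.approx(30.0)

    def test_mean_of_four_monthly_means(self):
        daily = {
            2016: make_daily("2016-07-01", np.r_[np.full(31, 29.8), np.full(31, 29.9)]),
            2017: make_daily("2017-07-01", np.r_[np.full(31, 29.9), np.full(31, 30.0)]),
        }
        assert compute_mmm_max(daily) == pytest.approx(29.9)

    def test_missing_month_raises(self):
        daily = {2016: make_daily("2016-07-01", np.full(31, 29.8))}  # no August
        with pytest.raises(InsufficientDataError):
            compute_mmm_max(daily)


class TestHotspots:
    @pytest.mark.parametrize(
        "mean,expected", [(31.3, 1.4), (29.9, 0.0), (28.5, -1.4)]
    )
    def test_sign_convention(self, mean, expected):
        hs = hs_series([mean - 29.9])
        assert hs.iloc[0] == pytest.approx(expected)

    def test_max_basis_switch(self):
        daily = make_daily("2016-07-01", [30.0], maxs=[31.0])
        cfg = ThermalConfig(mmm_max=29.9, hotspot_basis="max")
        assert hotspots(daily, cfg).iloc[0] == pytest.approx(1.1)


class TestMdhw:
    def test_hand_summed_example(self):
        hs = hs_series([1.4, 0, 1.0, 1.7, 0.5, 1.1, -0.9])
        running, mx = compute_mdhw(hs, CFG)
        assert mx == pytest.approx((1.4 + 1.0 + 1.7 + 1.1) / 7.0)
        assert running.iloc[-1] == pytest.approx(mx)

    def test_all_below_alpha_zero(self):
        _, mx = compute_mdhw(hs_series([0.5, 0.9, -2.0]), CFG)
        assert mx == 0.0

    def test_running_nondecreasing(self, rng):
        hs = hs_series(rng.normal(0, 1.5, size=62))
        running, _ = compute_mdhw(hs, CFG)
        assert (np.diff(running.to_numpy()) >= -1e-15).all()


class TestDhd:
    def test_hand_sum_of_positives(self):
        daily = make_daily("2016-07-01", 29.9 + np.array([0.5, -0.2, 1.2]))
        assert compute_dhd(daily, CFG) == pytest.approx(1.7)

    def test_at_reference_zero(self):
        daily = make_daily("2016-07-01", np.full(10, 29.9))
        assert compute_dhd(daily, CFG) == 0.0

    def test_dominates_seven_mdhw(self, rng):
        vals = rng.normal(0, 1.5, size=62)
        daily = make_daily("2016-07-01", 29.9 + vals)
        _, mx = compute_mdhw(hotspots(daily, CFG), CFG)
        assert compute_dhd(daily, CFG) >= 7.0 * mx - 1e-12


class TestCsa:
    @pytest.mark.parametrize(
        "vals,expected",
        [([1.0, 2.0], 1.5), ([0.0, 2.0, 0.0], 2.0), ([0.5, 0.9, 0.3], 0.0)],
    )
    def test_trapezoids(self, vals, expected):
        assert compute_csa(hs_series(vals), CFG) == pytest.approx(expected)

    def test_single_day_zero_with_warning(self):
        with pytest.warns(UserWarning, match="single-day"):
            assert compute_csa(hs_series([2.0]), CFG) == 0.0


class TestDhm:
    def test_only_qualifying_months(self):
        means = np.r_[np.full(31, 29.9 + 1.2), np.full(31, 29.9 + 0.8), np.full(30, 29.9 - 0.3)]
        daily = make_daily("2016-07-01", means)
        assert compute_dhm(daily, CFG) == pytest.approx(1.2)

    def test_two_qualifying_months_sum(self):
        means = np.r_[np.full(31, 30.9), np.full(31, 31.4)]
        daily = make_daily("2016-07-01", means)
        assert compute_dhm(daily, CFG) == pytest.approx(1.0 + 1.5)

    def test_none_qualifying(self):
        daily = make_daily("2016-07-01", np.full(62, 29.9))
        assert compute_dhm(daily, CFG) == 0.0


class TestAcute:
    def test_count_by_hand(self):
        hs = hs_series([1.5, 1.2, 1.0, 0.5, 0.2, 0.0, -0.5, -1.0, 0.9, 0.99])
        assert compute_acute(hs, 1.0) == pytest.approx(30.0)

    def test_no_exceedances(self):
        assert compute_acute(hs_series([0.0, -1.0]), 2.0) == 0.0


class TestMax3d:
    def test_sliding_means_by_hand(self):
        daily = make_daily("2016-07-01", [29, 30, 31, 32, 30])
        assert compute_max3d(daily, CFG) == pytest.approx(31.0)

    def test_constant(self):
        daily = make_daily("2016-07-01", np.full(5, 30.0))
        assert compute_max3d(daily, CFG) == pytest.approx(30.0)

    def test_two_days_error(self):
        daily = make_daily("2016-07-01", [30.0, 31.0])
        with pytest.raises(InsufficientDataError):
            compute_max3d(daily, CFG)

    def test_gap_breaks_run(self):
        valid = np.array([True, True, False, True, True, True])
        daily = make_daily("2016-07-01", [35, 35, 35, 30, 30, 30], valid=valid)
        # the hot pair is not a 3-day run; only the later run counts
        assert compute_max3d(daily, CFG) == pytest.approx(30.0)


class TestHeatingRate1:
    def test_ratio(self):
        daily = make_daily("2016-07-01", 29.9 + np.array([0.5, 1.5, -0.3]))
        assert compute_heating_rate1(daily, CFG) == pytest.approx(1.0)

    def test_single_term(self):
        daily = make_daily("2016-07-01", 29.9 + np.array([0.3, -0.1]))
        assert compute_heating_rate1(daily, CFG) == pytest.approx(0.3)

    def test_undefined_flagged(self):
        daily = make_daily("2016-07-01", np.full(5, 29.0))
        assert compute_heating_rate1(daily, CFG) is None


class TestDtrStats:
    def test_mean_by_hand(self):
        daily = make_daily("2016-07-01", np.full(3, 30.0), maxs=[31, 31, 33], mins=[30, 30, 30])
        mean, skew, kurt = dtr_stats(daily)
        assert mean == pytest.approx(5.0 / 3.0)

    def test_symmetric_skew_zero(self):
        daily = make_daily("2016-07-01", np.full(3, 30.0), maxs=[31, 32, 33], mins=[30, 30, 30])
        _, skew, _ = dtr_stats(daily)
        assert skew == pytest.approx(0.0)

    def test_constant_undefined(self):
        daily = make_daily("2016-07-01", np.full(5, 30.0), maxs=np.full(5, 31.0), mins=np.full(5, 30.0))
        mean, skew, kurt = dtr_stats(daily)
        assert mean == pytest.approx(1.0)
        assert skew is None and kurt is None


@settings(deadline=None, max_examples=50)
@given(
    vals=st.lists(st.floats(-2, 3, allow_nan=False), min_size=4, max_size=40),
    invalid_at=st.lists(st.integers(0, 39), max_size=8),
)
def test_indices_ignore_invalid_days(vals, invalid_at):
    """Inserting QC-failed days anywhere must not change any index."""
    base = make_daily("2016-07-05", 29.9 + np.asarray(vals))
    polluted_vals, valid = [], []
    j = 0
    for i, v in enumerate(vals):
        if i in invalid_at:
            polluted_vals.append(45.0 - 5.0)  # junk but in-band
            valid.append(False)
        polluted_vals.append(v)
        valid.append(True)
    # rebuild with shifted dates: invalid days occupy their own dates
    polluted = make_daily("2016-07-05", 29.9 + np.asarray(polluted_vals), valid=np.asarray(valid))
    cfg = CFG
    _, m1 = compute_mdhw(hotspots(base, cfg), cfg)
    _, m2 = compute_mdhw(hotspots(polluted, cfg), cfg)
    assert m1 == pytest.approx(m2, abs=1e-12)
    assert compute_dhd(base, cfg) == pytest.approx(compute_dhd(polluted, cfg), abs=1e-12)
    assert compute_acute(hotspots(base, cfg, "year"), 1.0) == pytest.approx(
        compute_acute(hotspots(polluted, cfg, "year"), 1.0), abs=1e-12
    )


def test_thermal_report_assembles(rng):
    daily = make_daily("2016-07-01", 29.9 + rng.normal(0, 0.8, size=62))
    rep = thermal_report(daily, CFG, 2016)
    assert rep.mdhw_max == pytest.approx(rep.mdhw_running.iloc[-1])
    d = rep.to_dict()
    assert set(d) >= {"mdhw_max", "dhd", "csa", "dhm", "acute1", "acute2", "max3d"}
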