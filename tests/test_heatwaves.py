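"""Heat wave definitions: heat index, thresholds, detectors, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heatmort import heatwaves as hw
from heatmort.units import c_to_f, f_to_c

from conftest import make_series


def rothfusz_oracle_f(t_f, rh):
    """Independent hand evaluation of the published regression (°F)."""
    return (
        -42.379
        + 2.04901523 * t_f
        + 10.14333127 * rh
        - 0.22475541 * t_f * rh
        - 0.00683783 * t_f * t_f
        - 0.05481717 * rh * rh
        + 0.00122874 * t_f * t_f * rh
        + 0.00085282 * t_f * rh * rh
        - 0.00000199 * t_f * t_f * rh * rh
    )


def dewpoint_for_rh(temp_c, rh):
    """Invert the Magnus formula for the dew point giving the wanted RH."""
    es = 6.112 * np.exp(17.67 * temp_c / (temp_c + 243.5))
    e = es * rh / 100.0
    ln = np.log(e / 6.112)
    return 243.5 * ln / (17.67 - ln)


class TestHeatIndex:
    def test_matches_independent_regression_at_90f_50rh(self):
        temp_c = f_to_c(90.0)
        hi = hw.heat_index(temp_c, dewpoint_for_rh(temp_c, 50.0))
        assert c_to_f(hi) == pytest.approx(rothfusz_oracle_f(90.0, 50.0), abs=0.05)

    def test_cold_limit_convention(self):
        for t in (-5.0, 0.0, 4.4):
            assert hw.heat_index(t, t - 5.0) == pytest.approx(t)

    def test_boundary_finite_and_above_simple(self):
        t = 26.7  # 80 °F applicability boundary
        hi = hw.heat_index(t, dewpoint_for_rh(t, 90.0))
        assert np.isfinite(hi)
        t_f, rh = c_to_f(t), 90.0
        simple = 0.5 * (t_f + 61.0 + (t_f - 68.0) * 1.2 + rh * 0.094)
        assert c_to_f(hi) >= simple - 1e-9

    def test_humidity_adjustments_match_oracle(self):
        # low-RH adjustment branch
        t_f, rh = 95.0, 10.0
        expected = rothfusz_oracle_f(t_f, rh) - ((13.0 - rh) / 4.0) * np.sqrt(
            (17.0 - abs(t_f - 95.0)) / 17.0
        )
        got = c_to_f(hw.heat_index(f_to_c(t_f), dewpoint_for_rh(f_to_c(t_f), rh)))
        assert got == pytest.approx(expected, abs=0.05)
        # high-RH adjustment branch
        t_f, rh = 84.0, 95.0
        expected = rothfusz_oracle_f(t_f, rh) + ((rh - 85.0) / 10.0) * ((87.0 - t_f) / 5.0)
        got = c_to_f(hw.heat_index(f_to_c(t_f), dewpoint_for_rh(f_to_c(t_f), rh)))
        assert got == pytest.approx(expected, abs=0.05)

    def test_unphysical_temperature_rejected(self):
        with pytest.raises(ValueError):
            hw.heat_index(70.0, 20.0)
        with pytest.raises(ValueError):
            hw.heat_index(-95.0, -100.0)


class TestComputeThresholds:
    def test_floor_binds_on_cool_county(self):
        series = make_series(np.full(100, 25.0))
        thr = hw.compute_thresholds(series)
        assert thr["thr_tavg"].iloc[0] == 26.7

    def test_percentile_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(28, 40, 100)
        series = make_series(values)
        thr = hw.compute_thresholds(series)
        v = np.sort(values)
        # linear interpolation between order statistics at p = 0.95
        h = 0.95 * (len(v) - 1)
        expected = v[int(h)] + (h - int(h)) * (v[int(h) + 1] - v[int(h)])
        assert thr["thr_tavg"].iloc[0] == pytest.approx(expected)

    def test_floor_below_percentile_is_inactive(self):
        series = make_series(np.linspace(30, 42, 100))
        thr_def = hw.compute_thresholds(series)
        thr_nofloor = hw.compute_thresholds(series, hw.HWDConfig(tavg_floor=-100.0))
        assert thr_def["thr_tavg"].iloc[0] == thr_nofloor["thr_tavg"].iloc[0]

    def test_t2_capped_at_t1(self):
        series = make_series(np.full(50, 20.0))  # both percentiles below the T1 floor
        thr = hw.compute_thresholds(series)
        assert (thr["tmax_t2"] <= thr["tmax_t1"]).all()

    def test_missing_county_is_error(self):
        series = make_series(np.full(10, 25.0))
        with pytest.raises(ValueError, match="C9"):
            hw.compute_thresholds(series, counties=["C1", "C9"])


class TestDetectRuns:
    def test_manual_enumeration_example(self):
        series = make_series([27, 28, 26, 29, 30, 31])
        events = hw.detect_runs(series, 26.7, "tavg_c", 2, "HWD_Tavg")
        assert len(events) == 2
        assert events["length_days"].tolist() == [2, 3]
        assert events["start_date"].tolist() == [
            pd.Timestamp("2001-06-01"),
            pd.Timestamp("2001-06-04"),
        ]

    def test_all_below_threshold(self):
        events = hw.detect_runs(make_series([20, 21, 22]), 26.7, "tavg_c", 2, "HWD_Tavg")
        assert events.empty

    def test_isolated_hot_day_dropped(self):
        events = hw.detect_runs(make_series([20, 30, 20]), 26.7, "tavg_c", 2, "HWD_Tavg")
        assert events.empty

    def test_strict_inequality_at_threshold(self):
        events = hw.detect_runs(make_series([26.7, 26.7, 26.7]), 26.7, "tavg_c", 2, "HWD_Tavg")
        assert events.empty

    def test_runs_do_not_cross_season_gap(self):
        a = make_series(np.full(3, 30.0), start="2001-09-28")
        b = make_series(np.full(3, 30.0), start="2002-05-01")
        events = hw.detect_runs(pd.concat([a, b], ignore_index=True), 26.7, "tavg_c", 2, "HWD_Tavg")
        assert len(events) == 2
        assert events["length_days"].tolist() == [3, 3]

    def test_mean_intensity_is_event_mean(self):
        events = hw.detect_runs(make_series([29.0, 31.0, 20.0]), 26.7, "tavg_c", 2, "HWD_Tavg")
        assert events["mean_intensity_c"].iloc[0] == pytest.approx(30.0)


class TestDetectHiDays:
    def _qualifying_series(self, n_hot):
        cool = make_series(np.full(2, 20.0))
        hot = make_series(np.full(n_hot, 38.0), start="2001-06-03", dew_offset=10.0, halfrange=6.0)
        return pd.concat([cool, hot], ignore_index=True)

    def test_consecutive_days_group_into_one_event(self):
        events = hw.detect_hi_days(self._qualifying_series(3))
        assert len(events) == 1
        assert events["length_days"].iloc[0] == 3
        assert events["definition"].iloc[0] == "HWD_HI"

    def test_below_high_threshold_not_a_heat_wave(self):
        series = make_series(np.full(3, 28.0), dew_offset=10.0)  # max HI ~ 33 °C
        assert hw.detect_hi_days(series).empty

    def test_flags_match_independent_daily_reevaluation(self):
        rng = np.random.default_rng(42)
        tavg = rng.uniform(15, 38, 1000)
        series = make_series(tavg, dew_offset=9.0, halfrange=5.7)
        events = hw.detect_hi_days(series)
        flagged = set()
        for _, ev in events.iterrows():
            for d in range(int(ev["length_days"])):
                flagged.add(ev["start_date"] + pd.Timedelta(days=d))
        cfg = hw.HWDConfig()
        for _, row in series.iterrows():
            low = hw.heat_index(row["tmin_c"], row["dewpoint_c"])
            high = hw.heat_index(row["tmax_c"], row["dewpoint_c"])
            qualifies = low >= cfg.hi_low_threshold and high >= cfg.hi_high_threshold
            assert qualifies == (row["date"] in flagged)

    def test_missing_dewpoint_is_error(self):
        series = make_series(np.full(3, 30.0)).drop(columns=["dewpoint_c"])
        with pytest.raises(ValueError, match="dew point"):
            hw.detect_hi_days(series)


def meehl_tebaldi_oracle(tmax, t1, t2, min_hot=3):
    """Exhaustive window enumeration with the same run/tie rules."""
    n = len(tmax)
    events = []
    i = 0
    while i < n:
        if tmax[i] > t2:
            j = i
            while j < n and tmax[j] > t2:
                j += 1
            best = None  # (length, start)
            for a in range(i, j):
                for b in range(a + 1, j + 1):
                    w = tmax[a:b]
                    if (w > t1).sum() >= min_hot and w.mean() > t1:
                        cand = (b - a, -a)
                        if best is None or cand > best:
                            best = cand
            if best is not None:
                events.append((-best[1], best[0]))
            i = j
        else:
            i += 1
    return events


def _mt_series(tmax_values):
    series = make_series(np.asarray(tmax_values, dtype=float) - 5.0, halfrange=5.0)
    thresholds = pd.DataFrame(
        {"county_id": ["C1"], "tmax_t1": [33.0], "tmax_t2": [31.0]}
    )
    return series, thresholds


class TestMeehlTebaldi:
    def test_minimal_three_day_event(self):
        series, thr = _mt_series([25, 34, 34, 34, 25])
        events = hw.detect_meehl_tebaldi(series, thr)
        assert len(events) == 1
        assert events["length_days"].iloc[0] == 3
        assert events["start_date"].iloc[0] == pd.Timestamp("2001-06-02")

    def test_two_hot_days_insufficient(self):
        series, thr = _mt_series([25, 34, 34, 25])
        assert hw.detect_meehl_tebaldi(series, thr).empty

    def test_window_extends_over_warm_shoulder(self):
        # shoulders above T2 join the event while the mean stays above T1
        series, thr = _mt_series([25, 32, 36, 36, 36, 32, 25])
        events = hw.detect_meehl_tebaldi(series, thr)
        assert len(events) == 1
        assert events["length_days"].iloc[0] == 5

    @settings(derandomize=True, deadline=None, max_examples=300)
    @given(
        st.lists(st.sampled_from([30.0, 32.0, 35.0]), min_size=1, max_size=20)
    )
    def test_equals_exhaustive_enumeration(self, tmax_values):
        series, thr = _mt_series(tmax_values)
        events = hw.detect_meehl_tebaldi(series, thr)
        expected = meehl_tebaldi_oracle(np.asarray(tmax_values), 33.0, 31.0)
        got = [
            ((ev["start_date"] - pd.Timestamp("2001-06-01")).days, ev["length_days"])
            for _, ev in events.iterrows()
        ]
        assert got == expected


class TestSummaries:
    def test_hand_arithmetic(self):
        events = pd.DataFrame(
            {
                "county_id": "C1",
                "definition": "HWD_Tavg",
                "year": 2001,
                "start_date": pd.Timestamp("2001-06-01"),
                "length_days": [2, 3, 4],
                "mean_intensity_c": 30.0,
            }
        )
        out = hw.summarize(events, n_years=2, n_counties=1)
        row = out.set_index("definition").loc["HWD_Tavg"]
        assert row["frequency"] == pytest.approx(1.5)
        assert row["duration_mean"] == pytest.approx(3.0)

    def test_schema_contains_all_four_definitions(self):
        out = hw.summarize(pd.DataFrame(columns=hw.EVENT_COLUMNS), 1, 1)
        assert out["definition"].tolist() == list(hw.HWD_KINDS)
        assert (out["frequency"] == 0).all()
        assert out["duration_mean"].isna().all()


@pytest.fixture(scope="module")
def warm_series():
    rng = np.random.default_rng(7)
    return make_series(rng.normal(26, 4, 153 * 2), dew_offset=9.0, halfrange=5.7)


class TestDefinitionInvariants:
    def _thresholds(self, series, config=hw.HWDConfig()):
        return hw.compute_thresholds(series, config)

    def test_warming_never_decreases_qualifying_days(self, warm_series):
        thr = self._thresholds(warm_series)
        warmer = warm_series.copy()
        for col in ("tavg_c", "tmax_c", "tmin_c", "dewpoint_c"):
            warmer[col] += 1.5
        for kind in ("HWD_HI", "HWD_Tavg", "HWD_Tmin"):
            base_days = hw.detect(warm_series, thr, hw.HWDConfig(), kind)["length_days"].sum()
            warm_days = hw.detect(warmer, thr, hw.HWDConfig(), kind)["length_days"].sum()
            assert warm_days >= base_days
        # the T_max definition reports one window per warm stretch, so its
        # event-day total is not monotone; the day-level criterion is
        t1 = thr.set_index("county_id")["tmax_t1"]
        base_hot = (warm_series["tmax_c"].to_numpy() > t1["C1"]).sum()
        warm_hot = (warmer["tmax_c"].to_numpy() > t1["C1"]).sum()
        assert warm_hot >= base_hot

    def test_events_disjoint_within_county_year(self, warm_series):
        thr = self._thresholds(warm_series)
        for kind in hw.HWD_KINDS:
            events = hw.detect(warm_series, thr, hw.HWDConfig(), kind)
            for (_, _), grp in events.groupby(["county_id", "year"]):
                grp = grp.sort_values("start_date")
                ends = grp["start_date"] + pd.to_timedelta(grp["length_days"], unit="D")
                assert (grp["start_date"].iloc[1:].to_numpy() >= ends.iloc[:-1].to_numpy()).all()

    def test_raising_floor_weakly_decreases_events(self, warm_series):
        low = hw.detect(
            warm_series, self._thresholds(warm_series, hw.HWDConfig(tavg_floor=20.0)),
            hw.HWDConfig(), "HWD_Tavg",
        )
        high = hw.detect(
            warm_series, self._thresholds(warm_series, hw.HWDConfig(tavg_floor=30.0)),
            hw.HWDConfig(), "HWD_Tavg",
        )
        assert len(high) <= len(low)

    def test_every_event_reverifies_its_criteria(self, warm_series):
        thr = self._thresholds(warm_series).set_index("county_id")
        cfg = hw.HWDConfig()
        day = pd.Timedelta(days=1)
        for kind in hw.HWD_KINDS:
            events = hw.detect(warm_series, thr.reset_index(), cfg, kind)
            for _, ev in events.iterrows():
                days = warm_series[
                    (warm_series["county_id"] == ev["county_id"])
                    & (warm_series["date"] >= ev["start_date"])
                    & (warm_series["date"] < ev["start_date"] + ev["length_days"] * day)
                ]
                assert len(days) == ev["length_days"]
                t = thr.loc[ev["county_id"]]
                if kind == "HWD_Tavg":
                    assert (days["tavg_c"] > t["thr_tavg"]).all()
                elif kind == "HWD_Tmin":
                    assert (days["tmin_c"] > t["thr_tmin"]).all()
                elif kind == "HWD_Tmax":
                    assert (days["tmax_c"] > t["tmax_t2"]).all()
                    assert (days["tmax_c"] > t["tmax_t1"]).sum() >= cfg.min_len_tmax
                    assert days["tmax_c"].mean() > t["tmax_t1"]
                else:
                    low = hw.heat_index(days["tmin_c"], days["dewpoint_c"])
                    high = hw.heat_index(days["tmax_c"], days["dewpoint_c"])
                    assert (low >= cfg.hi_low_threshold).all()
                    assert (high >= cfg.hi_high_threshold).all()
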