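from datetime import date, datetime, time, timedelta

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hbpnotify.readings import (
    BPMeasurement,
    assign_period,
    averages_frame,
    dedup_first_per_period,
    filter_window,
    period_averages,
)


def bp(ts: str, sbp: int = 130, dbp: int = 80, pid: str = "p1") -> BPMeasurement:
    return BPMeasurement(pid, datetime.fromisoformat(ts), sbp, dbp)


@pytest.mark.parametrize(
    "ts, period, logical_day",
    [
        ("2014-03-01T06:30", "morning", date(2014, 3, 1)),
        ("2014-03-02T02:00", "evening", date(2014, 3, 1)),  # wraps to previous day
        ("2014-03-01T11:00", "midday", date(2014, 3, 1)),  # half-open boundary
        ("2014-03-01T04:00", "morning", date(2014, 3, 1)),
        ("2014-03-01T16:00", "evening", date(2014, 3, 1)),
        ("2014-03-01T03:59", "evening", date(2014, 2, 28)),
        ("2014-03-01T10:59", "morning", date(2014, 3, 1)),
        ("2014-03-01T23:59", "evening", date(2014, 3, 1)),
    ],
)
def test_assign_period_windows(ts, period, logical_day):
    assert assign_period(datetime.fromisoformat(ts)) == (period, logical_day)


@given(minutes=st.integers(0, 24 * 60 - 1), day=st.integers(0, 27))
def test_every_clock_minute_maps_to_exactly_one_period(minutes, day):
    ts = datetime(2014, 3, 1) + timedelta(days=day, minutes=minutes)
    period, logical_day = assign_period(ts)
    assert period in ("morning", "midday", "evening")
    # logical day is the calendar day except in the early-morning wrap
    expected = ts.date() - timedelta(days=1) if ts.time() < time(4) else ts.date()
    assert logical_day == expected


def test_measurement_invariant_rejects_nonphysical_pressures():
    with pytest.raises(ValueError):
        BPMeasurement("p1", datetime(2014, 3, 1, 8), 80, 130)
    with pytest.raises(ValueError):
        BPMeasurement("p1", datetime(2014, 3, 1, 8), 130, 0)


class TestDedup:
    def test_first_of_same_period_kept(self):
        first, second = bp("2014-03-01T06:00", 130, 80), bp("2014-03-01T07:00", 150, 95)
        assert dedup_first_per_period([second, first]) == [first]

    def test_single_measurement_unchanged(self):
        m = bp("2014-03-01T06:00")
        assert dedup_first_per_period([m]) == [m]

    def test_post_midnight_reading_shares_previous_evening_cell(self):
        late = bp("2014-03-01T23:00")
        after_midnight = bp("2014-03-02T02:00")
        assert dedup_first_per_period([late, after_midnight]) == [late]

    def test_identical_timestamps_keep_first_input_row_with_warning(self, caplog):
        a = bp("2014-03-01T06:00", 130, 80)
        b = bp("2014-03-01T06:00", 150, 95)
        with caplog.at_level("WARNING"):
            assert dedup_first_per_period([a, b]) == [a]
        assert "duplicate timestamp" in caplog.text

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 13),
                st.integers(0, 24 * 60 - 1),
                st.integers(90, 200),
            ),
            max_size=40,
        )
    )
    def test_idempotent_and_capped(self, raw):
        ms = [
            BPMeasurement(
                "p1",
                datetime(2014, 3, 1) + timedelta(days=d, minutes=minute),
                sbp,
                sbp - 40,
            )
            for d, minute, sbp in raw
        ]
        once = dedup_first_per_period(ms)
        assert dedup_first_per_period(once) == once
        # at most one retained reading per (logical day, period) over a
        # 15-logical-day span (day-0 early readings wrap backwards)
        per_period = {}
        for m in once:
            period, day = assign_period(m.timestamp)
            key = (day, period)
            per_period[key] = per_period.get(key, 0) + 1
        assert all(v == 1 for v in per_period.values())


class TestPeriodAverages:
    def test_simple_mean(self):
        ms = [
            bp("2014-03-01T06:00", 180, 110),
            bp("2014-03-02T06:00", 190, 114),
            bp("2014-03-03T06:00", 185, 112),
        ]
        morning = period_averages(ms)[0]
        assert morning.period == "morning"
        assert morning.n_used == 3
        assert morning.mean_sbp == pytest.approx(185.0)
        assert morning.mean_dbp == pytest.approx(112.0)

    def test_empty_period_has_absent_means(self):
        out = period_averages([bp("2014-03-01T06:00")])
        evening = next(a for a in out if a.period == "evening")
        assert evening.n_used == 0
        assert evening.mean_sbp is None and evening.mean_dbp is None

    def test_empty_input_gives_three_zero_records(self):
        out = period_averages([])
        assert [a.period for a in out] == ["morning", "midday", "evening"]
        assert all(a.n_used == 0 for a in out)

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 13),
                st.integers(0, 24 * 60 - 1),
                st.integers(90, 200),
                st.integers(50, 89),
            ),
            max_size=100,
        )
    )
    def test_matches_naive_double_loop_oracle(self, raw):
        ms = [
            BPMeasurement(
                "p1",
                datetime(2014, 3, 1) + timedelta(days=d, minutes=minute),
                sbp,
                dbp,
            )
            for d, minute, sbp, dbp in raw
        ]
        # independent oracle: walk (day, period) cells, keep earliest, average
        cells = {}
        for m in sorted(ms, key=lambda m: m.timestamp):
            key = assign_period(m.timestamp)[::-1]
            if key not in cells:
                cells[key] = m
        for avg in period_averages(ms):
            kept = [m for (day, p), m in cells.items() if p == avg.period]
            assert avg.n_used == len(kept)
            if kept:
                assert avg.mean_sbp == pytest.approx(
                    sum(m.sbp for m in kept) / len(kept)
                )
                assert avg.mean_dbp == pytest.approx(
                    sum(m.dbp for m in kept) / len(kept)
                )


def test_filter_window_drops_out_of_window_readings(caplog):
    inside = bp("2014-03-05T08:00")
    late = bp("2014-03-20T08:00")
    early_wrap = bp("2014-03-01T02:00")  # evening of Feb 28, outside
    with caplog.at_level("WARNING"):
        kept = filter_window([inside, late, early_wrap], start=date(2014, 3, 1))
    assert kept == [inside]
    assert "out-of-window" in caplog.text


def test_averages_frame_orders_participants_and_periods():
    ms = [bp("2014-03-01T06:00", pid="b"), bp("2014-03-01T12:00", pid="a")]
    df = averages_frame(ms)
    assert list(df["participant_id"]) == ["a"] * 3 + ["b"] * 3
    assert list(df["period"]) == ["morning", "midday", "evening"] * 2
    assert df.loc[(df.participant_id == "a") & (df.period == "midday"), "n_used"].item() == 1
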