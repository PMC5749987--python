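"""Event-relative day labelling, eligibility, and hour/day windows."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from blastpam.activity import hourly_mean_activity, score_frame
from blastpam.events import TrainingEvent, UndetEvent
from blastpam.scene import ActivityModelParams, build_recording_schedule, simulate_counts
from blastpam.windows import (
    DayLabel,
    DayNightScheme,
    check_baseline_eligibility,
    day_scale_series,
    hour_scale_windows,
    label_event_days,
    paired_day_values,
)


def _event(days, event_id=1, hour=11):
    return TrainingEvent(
        event_id=event_id,
        undets=[
            UndetEvent(onset_time=f"2013-06-{d:02d} {hour:02d}:00", reverb_duration=1.0)
            for d in days
        ],
    )


class TestLabelEventDays:
    def test_single_day_event(self):
        labels = label_event_days(_event([10]))
        assert labels == {
            date(2013, 6, 9): DayLabel.DAY_BEFORE,
            date(2013, 6, 10): DayLabel.DAY_OF,
            date(2013, 6, 11): DayLabel.DAY_AFTER,
            date(2013, 6, 12): DayLabel.SECOND_DAY_AFTER,
        }

    def test_after_days_anchor_on_final_undet(self):
        labels = label_event_days(_event([10, 11]))
        assert labels[date(2013, 6, 12)] == DayLabel.DAY_AFTER
        assert labels[date(2013, 6, 13)] == DayLabel.SECOND_DAY_AFTER
        assert labels[date(2013, 6, 11)] == DayLabel.DAY_OF

    def test_three_day_event_spans_six_days(self):
        labels = label_event_days(_event([10, 11, 12]))
        assert len(labels) == 6
        assert sorted(labels) == [date(2013, 6, d) for d in range(9, 15)]

    def test_labelling_is_a_partition(self):
        labels = label_event_days(_event([10, 11, 12]))
        assert len(set(labels.keys())) == len(labels)


class TestEligibility:
    def test_recent_previous_event_blocks(self):
        prev = _event([7], event_id=1)   # ended 3 days before the 10th
        cur = _event([10], event_id=2)
        assert not check_baseline_eligibility(cur, [prev, cur])

    def test_older_previous_event_allows(self):
        prev = _event([6], event_id=1)   # ended 4 days before the 10th
        cur = _event([10], event_id=2)
        assert check_baseline_eligibility(cur, [prev, cur])

    def test_first_event_with_data_is_eligible(self):
        cur = _event([10])
        assert check_baseline_eligibility(cur, [cur])

    def test_missing_baseline_recordings_block(self):
        cur = _event([10])
        assert not check_baseline_eligibility(cur, [cur], recorded_dates=set())
        assert check_baseline_eligibility(
            cur, [cur], recorded_dates={date(2013, 6, 9)}
        )

    def test_extra_undet_only_flips_towards_ineligible(self):
        """Monotonicity: adding an UNDET in the pre-window never makes an
        ineligible event eligible."""
        cur = _event([10], event_id=2)
        for d in range(7, 10):
            prev = _event([d], event_id=1)
            assert not check_baseline_eligibility(cur, [prev, cur])


def _hourly_from_indices(spec: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for hour, indices in spec.items():
        t0 = pd.Timestamp(hour)
        for i, v in enumerate(indices):
            rows.append({"site_id": "B", "start": t0 + pd.Timedelta(minutes=6 * i),
                         "index": v})
    return hourly_mean_activity(pd.DataFrame(rows))


class TestHourScaleWindows:
    def test_silent_hours_sum_to_zero(self):
        hourly = _hourly_from_indices(
            {f"2013-06-10 {h}:00": [0.0] * 10 for h in (9, 11, 12, 13)}
        )
        u = UndetEvent(onset_time="2013-06-10 10:30", reverb_duration=1.0)
        assert hour_scale_windows(u, hourly) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_sums(self):
        hourly = _hourly_from_indices(
            {
                "2013-06-10 09:00": [2.0] * 10,
                "2013-06-10 11:00": [1.0] * 10,
                "2013-06-10 12:00": [1.0] * 10,
                "2013-06-10 13:00": [1.0] * 10,
            }
        )
        u = UndetEvent(onset_time="2013-06-10 10:30", reverb_duration=1.0)
        assert hour_scale_windows(u, hourly) == (20.0, 10.0, 10.0, 10.0)

    def test_hour_before_is_the_previous_clock_hour(self):
        hourly = _hourly_from_indices({"2013-06-10 12:00": [3.0] * 5})
        u = UndetEvent(onset_time="2013-06-10 13:05", reverb_duration=1.0)
        sums = hour_scale_windows(u, hourly)
        assert sums[0] == 15.0  # 12:00-12:59 block
        assert all(np.isnan(s) for s in sums[1:])  # missing, not zero


class TestDayScaleSeries:
    def test_constant_index_gives_zero_differences(self):
        sch = build_recording_schedule("2013-06-08", "2013-06-13")
        rec = sch.assign(index=2.0)
        hourly = hourly_mean_activity(rec)
        table = day_scale_series(_event([10]), hourly)
        assert np.allclose(table["mean_activity"], 2.0)
        before, of = paired_day_values(
            table.assign(event_id=1), DayLabel.DAY_OF.value, "day"
        )
        assert np.allclose(of - before, 0.0)

    def test_night_block_attributed_to_starting_date(self):
        # activity only 00:00-05:59 on June 11 must land in June 10's night
        sch = build_recording_schedule("2013-06-09", "2013-06-13")
        rec = sch.assign(index=0.0)
        early = (rec["start"].dt.day == 11) & (rec["start"].dt.hour < 6)
        rec.loc[early, "index"] = 4.0
        hourly = hourly_mean_activity(rec)
        table = day_scale_series(_event([10]), hourly)
        night_of = table[(table["day_label"] == "day_of") & (table["block"] == "night")]
        assert night_of["mean_activity"].iloc[0] > 0

    def test_every_hour_belongs_to_one_block_of_one_date(self):
        scheme = DayNightScheme()
        from blastpam.windows import _block_hours

        seen = {}
        for d in [date(2013, 6, 9), date(2013, 6, 10)]:
            for block in ("day", "night"):
                for h in _block_hours(d, block, scheme):
                    assert h not in seen, f"{h} claimed twice"
                    seen[h] = (d, block)
        # the two days' blocks tile 48 distinct hours
        assert len(seen) == 48

    def test_interior_days_of_multiday_event_are_day_of(self):
        sch = build_recording_schedule("2013-06-08", "2013-06-16")
        rec = sch.assign(index=1.0)
        hourly = hourly_mean_activity(rec)
        table = day_scale_series(_event([10, 11, 12]), hourly)
        day_of = table[(table["day_label"] == "day_of") & (table["block"] == "day")]
        assert day_of["n_hours"].iloc[0] == 36  # 3 days x 12 daytime hours

    def test_block_with_no_recordings_stays_missing(self):
        sch = build_recording_schedule("2013-06-09", "2013-06-12")  # no 2nd-day-after
        rec = sch.assign(index=1.0)
        hourly = hourly_mean_activity(rec)
        table = day_scale_series(_event([10]), hourly)
        sda = table[(table["day_label"] == "second_day_after") & (table["block"] == "day")]
        assert np.isnan(sda["mean_activity"].iloc[0])
        assert sda["n_hours"].iloc[0] == 0

    def test_daytime_suppression_shows_in_day_block_only(self):
        """Simulator with daytime-only suppression: the day-of daytime mean
        drops below baseline while night means stay level (within MC error
        over 60 events)."""
        events, scheds = [], []
        t0 = pd.Timestamp("2013-05-02")
        for i in range(60):
            day = t0 + pd.Timedelta(days=6 * i)
            events.append(
                TrainingEvent(
                    event_id=i + 1,
                    undets=[UndetEvent(onset_time=day + pd.Timedelta(hours=6),
                                       reverb_duration=2.0)],
                )
            )
            scheds.append(build_recording_schedule(day - pd.Timedelta(days=1),
                                                   day + pd.Timedelta(days=3)))
        schedule = pd.concat(scheds, ignore_index=True)
        p = ActivityModelParams(seed=0, suppression=0.3, rebound=1.0)
        counts = simulate_counts(schedule, p, events, rng=np.random.default_rng(0))
        counts["index"] = score_frame(counts)
        hourly = hourly_mean_activity(counts)
        from blastpam.windows import day_scale_table

        table = day_scale_table(events, hourly, require_baseline=False)
        b_day, o_day = paired_day_values(table, "day_of", "day")
        b_night, o_night = paired_day_values(table, "day_of", "night")
        assert np.mean(o_day - b_day) < -0.2
        night_shift = np.mean(o_night - b_night)
        se = np.std(o_night - b_night, ddof=1) / np.sqrt(len(b_night))
        assert abs(night_shift) < 3 * se
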