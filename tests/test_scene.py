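"""Scene simulator: schedules, count models, rendered waveforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blastpam.detector import DetectorConfig, detect_transients
from blastpam.events import TrainingEvent, UndetEvent
from blastpam.scene import (
    ActivityModelParams,
    DutyCycle,
    WaveformSpec,
    build_recording_schedule,
    simulate_counts,
    synthesize_waveform,
)


class TestSchedule:
    def test_half_duty_cycle_gives_half_coverage(self):
        sch = build_recording_schedule(
            "2013-01-01", "2013-01-01 01:00", DutyCycle(180, 360, 0)
        )
        assert len(sch) == 10
        covered = sch["duration_s"].sum()
        assert covered / 3600.0 == 0.5

    def test_continuous_duty_cycle_has_no_gaps(self):
        sch = build_recording_schedule(
            "2013-01-01", "2013-01-01 01:00", DutyCycle(360, 360, 0)
        )
        ends = sch["start"] + pd.to_timedelta(sch["duration_s"], unit="s")
        gaps = (sch["start"].iloc[1:].to_numpy() - ends.iloc[:-1].to_numpy())
        assert (gaps == np.timedelta64(0)).all()
        assert sch["duration_s"].sum() == 3600

    def test_complementary_offsets_tile_the_span(self):
        a = build_recording_schedule("2013-01-01", "2013-01-01 01:00", DutyCycle(180, 360, 0))
        b = build_recording_schedule("2013-01-01", "2013-01-01 01:00", DutyCycle(180, 360, 180))
        both = pd.concat([a, b]).sort_values("start")
        ends = both["start"] + pd.to_timedelta(both["duration_s"], unit="s")
        gaps = both["start"].iloc[1:].to_numpy() - ends.iloc[:-1].to_numpy()
        assert (gaps == np.timedelta64(0)).all()  # no gap, no overlap
        assert both["duration_s"].sum() == 3600

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            build_recording_schedule("2013-01-02", "2013-01-01")

    @given(
        cycles=st.integers(min_value=1, max_value=48),
        on=st.integers(min_value=30, max_value=360),
    )
    @settings(max_examples=30, deadline=None)
    def test_coverage_exact_for_whole_cycles(self, cycles, on):
        duty = DutyCycle(on, 360, 0)
        span = cycles * 360
        sch = build_recording_schedule(
            "2013-01-01", pd.Timestamp("2013-01-01") + pd.Timedelta(seconds=span), duty
        )
        assert sch["duration_s"].sum() / span == pytest.approx(on / 360.0)

    def test_duty_cycle_invariants(self):
        with pytest.raises(ValueError):
            DutyCycle(400, 360)
        with pytest.raises(ValueError):
            DutyCycle(180, 360, offset=360)


def _two_day_event_scene():
    sch = build_recording_schedule("2013-06-01", "2013-06-03")
    ev = [
        TrainingEvent(
            event_id=1,
            undets=[UndetEvent(onset_time="2013-06-02 06:00", reverb_duration=4.0)],
        )
    ]
    return sch, ev


class TestSimulateCounts:
    def test_reproducible_for_fixed_seed(self):
        sch, ev = _two_day_event_scene()
        p = ActivityModelParams(seed=7)
        a = simulate_counts(sch, p, ev)
        b = simulate_counts(sch, p, ev)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_schedule_gives_empty_output(self):
        sch = build_recording_schedule("2013-06-01", "2013-06-02").iloc[:0]
        out = simulate_counts(sch, ActivityModelParams(seed=0))
        assert len(out) == 0
        assert set(["whistles", "burst_pulses", "click_rate_hz"]) <= set(out.columns)

    def test_silent_ocean_when_presence_zero(self):
        sch, ev = _two_day_event_scene()
        p = ActivityModelParams(seed=1, presence_prob_day=0.0, presence_prob_night=0.0)
        out = simulate_counts(sch, p, ev)
        assert (out["whistles"] == 0).all()
        assert (out["burst_pulses"] == 0).all()
        assert (out["click_rate_hz"] == 0).all()

    def test_negative_rates_rejected(self):
        sch, _ = _two_day_event_scene()
        with pytest.raises(ValueError):
            simulate_counts(sch, ActivityModelParams(seed=0, base_rate=-1.0))

    def test_null_response_leaves_day_of_unchanged(self):
        """suppression = rebound = 1: day-of and baseline daytime means agree
        in law; Monte-Carlo means differ by < 3 standard errors."""
        sch, ev = _two_day_event_scene()
        day_hours = sch["start"].dt.hour.between(6, 17)
        day1 = sch["start"].dt.day == 1
        base_means, of_means = [], []
        for s in range(300):
            p = ActivityModelParams(seed=s, suppression=1.0, rebound=1.0)
            out = simulate_counts(sch, p, ev, rng=np.random.default_rng(s))
            base_means.append(out.loc[day_hours & day1, "whistles"].mean())
            of_means.append(out.loc[day_hours & ~day1, "whistles"].mean())
        base, of = np.array(base_means), np.array(of_means)
        se = np.sqrt(base.var() / len(base) + of.var() / len(of))
        assert abs(base.mean() - of.mean()) < 3 * se

    def test_suppression_sets_mean_count_ratio(self):
        """suppression = 0.4 with the blast at 06:00: the day-of daytime
        whistle mean is 0.4x the baseline daytime mean (empirical oracle
        over 500 replicate simulations)."""
        sch, ev = _two_day_event_scene()
        day_hours = sch["start"].dt.hour.between(6, 17)
        day1 = sch["start"].dt.day == 1
        tot_b = tot_o = 0.0
        for s in range(500):
            p = ActivityModelParams(seed=s, suppression=0.4)
            out = simulate_counts(sch, p, ev, rng=np.random.default_rng(s))
            tot_b += out.loc[day_hours & day1, "whistles"].mean()
            tot_o += out.loc[day_hours & ~day1, "whistles"].mean()
        assert tot_o / tot_b == pytest.approx(0.4, abs=0.04)

    def test_monthly_means_follow_seasonal_curve(self):
        """Spearman correlation >= 0.9 between the seasonal curve and
        realized monthly detection means over 50 replicates."""
        from scipy.stats import spearmanr

        from blastpam.activity import score_frame
        from blastpam.occurrence import daily_detections, monthly_summary

        sch = build_recording_schedule("2013-01-01", "2014-01-01")
        p = ActivityModelParams(seed=0)
        monthly = np.zeros(12)
        for s in range(50):
            out = simulate_counts(sch, p, [], rng=np.random.default_rng(s))
            out["index"] = score_frame(out)
            m = monthly_summary(daily_detections(out))
            monthly += m.set_index("month")["mean_detections"].reindex(range(1, 13)).to_numpy()
        rho = spearmanr(monthly, p.seasonal_curve).statistic
        assert rho >= 0.9


class TestWaveform:
    def test_deterministic_for_fixed_seed(self):
        spec = WaveformSpec(sample_rate=4000, duration=10, transient_onset=5)
        a = synthesize_waveform(spec, seed=3)
        b = synthesize_waveform(spec, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_envelope_decay_matches_closed_form(self, detector_cfg):
        """Time for a +30 dB transient to decay to ambient + 6 dB is
        tau * ln(10^(30/20) / 10^(6/20)) = 2.763 tau; the detector-measured
        duration agrees within +-10%."""
        from blastpam.detector import measure_reverb_duration

        for tau in (1.0, 3.0):
            spec = WaveformSpec(
                sample_rate=4000, duration=90, transient_onset=40,
                transient_peak_level=30, reverb_time_constant=tau,
            )
            w = synthesize_waveform(spec, seed=11)
            d, censored = measure_reverb_duration(w, 4000, 40.0, detector_cfg)
            assert not censored
            assert d == pytest.approx(2.763 * tau, rel=0.10)

    def test_no_transient_means_no_detections(self, detector_cfg):
        spec = WaveformSpec(sample_rate=4000, duration=60)
        w = synthesize_waveform(spec, seed=5)
        assert detect_transients(w, 4000, detector_cfg) == []

    def test_two_separated_transients_detected_separately(self, detector_cfg):
        spec = WaveformSpec(sample_rate=4000, duration=90, transient_onset=35,
                            transient_peak_level=30, reverb_time_constant=0.5)
        w = synthesize_waveform(spec, seed=6)
        spec2 = WaveformSpec(sample_rate=4000, duration=90, transient_onset=65,
                             transient_peak_level=30, reverb_time_constant=0.5)
        w2 = synthesize_waveform(spec2, seed=7)
        combined = w + (w2 - synthesize_waveform(
            WaveformSpec(sample_rate=4000, duration=90), seed=7))
        events = detect_transients(combined, 4000, detector_cfg)
        assert len(events) == 2

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            WaveformSpec(sample_rate=0)
        with pytest.raises(ValueError):
            WaveformSpec(transient_onset=20, duration=10)
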