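import numpy as np
import pandas as pd
import pytest

from blastpam.detector import DetectorConfig
from blastpam.events import TrainingEvent, UndetEvent
from blastpam.scene import build_recording_schedule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def detector_cfg():
    # shorter background window than the field default, matched to the
    # compact synthetic recordings used in tests
    return DetectorConfig(background_window=20.0)


@pytest.fixture(scope="session")
def event_windows_scene():
    """31 single-day training events (blast at 10:05) with recording
    coverage from the day before through the second day after each."""
    events, scheds = [], []
    t0 = pd.Timestamp("2013-01-05")
    for i in range(31):
        day = t0 + pd.Timedelta(days=10 * i)
        onset = day + pd.Timedelta(hours=10, minutes=5)
        events.append(
            TrainingEvent(
                event_id=i + 1,
                undets=[UndetEvent(onset_time=onset, reverb_duration=4.0)],
            )
        )
        scheds.append(
            build_recording_schedule(
                day - pd.Timedelta(days=1), day + pd.Timedelta(days=3)
            )
        )
    schedule = pd.concat(scheds, ignore_index=True)
    return events, schedule
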