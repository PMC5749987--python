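"""Detonation events and their grouping into multi-day training events.

An underwater detonation (UNDET) appears on a hydrophone as an impulsive
transient followed by seconds of reverberation.  Its size class is assigned
from the reverberation duration alone: small (0-2 s), medium (2-7 s) and
large (7 s and up).  One or more UNDETs on one to a few consecutive days
form a *training event*; the response analysis anchors its comparison
windows on the first and last UNDET days of each training event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import pandas as pd

__all__ = [
    "UndetEvent",
    "TrainingEvent",
    "classify_size",
    "group_into_training_events",
]

#: size-class boundaries in seconds; half-open intervals [0, 2), [2, 7), [7, inf)
SIZE_BOUNDS = (2.0, 7.0)
SIZE_LABELS = ("small", "medium", "large")


def classify_size(reverb_duration: float) -> str:
    """Map a reverberation duration (s) to a size class.

    The intervals are half-open, ``[0, 2) -> small``, ``[2, 7) -> medium``,
    ``[7, inf) -> large``, so every nonnegative duration receives exactly
    one class and the boundaries 2.0 s and 7.0 s fall in the upper class.
    """
    d = float(reverb_duration)
    if d < 0:
        raise ValueError(f"reverb_duration must be >= 0, got {d}")
    if d < SIZE_BOUNDS[0]:
        return "small"
    if d < SIZE_BOUNDS[1]:
        return "medium"
    return "large"


@dataclass(frozen=True)
class UndetEvent:
    """A single detected underwater detonation.

    Parameters
    ----------
    onset_time : pandas.Timestamp
        Transient onset (naive local time).
    peak_level : float
        Peak envelope level in dB above the pre-event background.
    reverb_duration : float
        Seconds from onset until the envelope stays below background + 6 dB.
    size_class : str
        One of ``small``/``medium``/``large``; derived from
        ``reverb_duration`` when not given.
    censored : bool
        True when the recording ended before the envelope decayed, so the
        duration (and class) is a lower bound.
    """

    onset_time: pd.Timestamp
    peak_level: float = 0.0
    reverb_duration: float = 0.0
    size_class: str = ""
    censored: bool = False

    def __post_init__(self):
        object.__setattr__(self, "onset_time", pd.Timestamp(self.onset_time))
        if self.reverb_duration < 0:
            raise ValueError("reverb_duration must be >= 0")
        if not self.size_class:
            object.__setattr__(
                self, "size_class", classify_size(self.reverb_duration)
            )

    @property
    def day(self) -> date:
        return self.onset_time.date()

    @property
    def size_ordinal(self) -> int:
        """0 = none, 1 = small, 2 = medium, 3 = large."""
        return SIZE_LABELS.index(self.size_class) + 1


@dataclass
class TrainingEvent:
    """One to a few consecutive days of detonations, analysed as a unit."""

    event_id: int
    undets: list[UndetEvent] = field(default_factory=list)

    def __post_init__(self):
        if not self.undets:
            raise ValueError("a TrainingEvent requires at least one UNDET")
        self.undets = sorted(self.undets, key=lambda u: u.onset_time)

    @property
    def first_undet_day(self) -> date:
        return self.undets[0].day

    @property
    def last_undet_day(self) -> date:
        return self.undets[-1].day

    @property
    def undet_days(self) -> list[date]:
        """Sorted distinct calendar days containing at least one UNDET."""
        return sorted({u.day for u in self.undets})


def group_into_training_events(
    undets: list[UndetEvent], max_gap_days: int = 1
) -> list[TrainingEvent]:
    """Group time-sorted UNDETs into training events.

    UNDETs whose calendar days are separated by at most ``max_gap_days``
    days belong to the same training event.  The default of 1 groups
    detonations on consecutive calendar days, matching exercises that run
    over one to three days.
    """
    if max_gap_days < 0:
        raise ValueError("max_gap_days must be >= 0")
    undets = sorted(undets, key=lambda u: u.onset_time)
    events: list[TrainingEvent] = []
    current: list[UndetEvent] = []
    for u in undets:
        if current and (u.day - current[-1].day) > timedelta(days=max_gap_days):
            events.append(TrainingEvent(event_id=len(events) + 1, undets=current))
            current = []
        current.append(u)
    if current:
        events.append(TrainingEvent(event_id=len(events) + 1, undets=current))
    return events
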