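"""Event-relative comparison windows at hour and day scales.

Analysis windows are anchored to each training event: the *day before*
(baseline) is the calendar day before the first detonation; all detonation
days are the *day of*; the *day after* and *second day after* follow the
final detonation.  Within days, activity is split into daytime
(06:00-17:59 by default) and night (18:00-05:59, attributed to the date
the night starts on).  Hour-scale comparisons use whole clock hours around
each detonation.

Missing data stay missing (NaN): an hour without recordings is never
imputed as zero activity, because index 0 is itself a valid observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from enum import Enum

import numpy as np
import pandas as pd

from .events import TrainingEvent, UndetEvent

__all__ = [
    "DayLabel",
    "DayNightScheme",
    "label_event_days",
    "check_baseline_eligibility",
    "hour_scale_windows",
    "day_scale_series",
    "day_scale_table",
]


class DayLabel(str, Enum):
    DAY_BEFORE = "day_before"
    DAY_OF = "day_of"
    DAY_AFTER = "day_after"
    SECOND_DAY_AFTER = "second_day_after"


@dataclass(frozen=True)
class DayNightScheme:
    """Day/night clock-hour partition.

    ``standard`` daytime is 06:00-17:59; the distant-site day-of analysis
    uses a ``array_day_of`` variant starting at 10:00 because most
    detonations happen between 10:00 and 17:59.
    """

    day_start: int = 6
    day_end: int = 18  # exclusive
    variant: str = "standard"

    def __post_init__(self):
        if not (0 <= self.day_start < self.day_end <= 24):
            raise ValueError("require 0 <= day_start < day_end <= 24")

    def is_day_hour(self, hour: int) -> bool:
        return self.day_start <= hour < self.day_end


ARRAY_DAY_OF_SCHEME = DayNightScheme(day_start=10, day_end=18, variant="array_day_of")


def label_event_days(event: TrainingEvent) -> dict[date, DayLabel]:
    """Map calendar dates to their labels for one training event.

    All detonation days (first through last, inclusive) are ``day_of``;
    the two days following the final detonation are ``day_after`` and
    ``second_day_after``.  The labelling is a partition: no date gets two
    labels.
    """
    labels: dict[date, DayLabel] = {}
    labels[event.first_undet_day - timedelta(days=1)] = DayLabel.DAY_BEFORE
    d = event.first_undet_day
    while d <= event.last_undet_day:
        labels[d] = DayLabel.DAY_OF
        d += timedelta(days=1)
    labels[event.last_undet_day + timedelta(days=1)] = DayLabel.DAY_AFTER
    labels[event.last_undet_day + timedelta(days=2)] = DayLabel.SECOND_DAY_AFTER
    return labels


def check_baseline_eligibility(
    event: TrainingEvent,
    all_events: list[TrainingEvent],
    recorded_dates: set[date] | None = None,
) -> bool:
    """True when the event has a clean 3-day pre-event baseline.

    An event is ineligible when any detonation (from any event) falls in
    the 3 calendar days before its first detonation day, or when
    ``recorded_dates`` is supplied and contains no data on the day before.
    """
    window_start = event.first_undet_day - timedelta(days=3)
    for other in all_events:
        for u in other.undets:
            if window_start <= u.day < event.first_undet_day:
                return False
    if recorded_dates is not None:
        if (event.first_undet_day - timedelta(days=1)) not in recorded_dates:
            return False
    return True


def _hour_sum(hourly: pd.DataFrame, hour: pd.Timestamp) -> float:
    """Sum of segment indices in a clock hour (maa_raw * n_segments); NaN if absent."""
    row = hourly.loc[hourly["hour_start"] == hour]
    if len(row) == 0 or row["maa_raw"].isna().all():
        return np.nan
    r = row.iloc[0]
    return float(r["maa_raw"] * r["n_segments"])


def hour_scale_windows(
    undet: UndetEvent, hourly: pd.DataFrame
) -> tuple[float, float, float, float]:
    """Summed activity for the clock hour before a detonation and the three after.

    The windows are whole clock hours relative to the detonation's clock
    hour: a blast at 13:05 has hour-before 12:00-12:59 and hours after
    14:00, 15:00 and 16:00.  A missing hour yields NaN for that window.
    """
    h0 = undet.onset_time.floor("h")
    hours = [h0 - pd.Timedelta(hours=1)] + [
        h0 + pd.Timedelta(hours=k) for k in (1, 2, 3)
    ]
    return tuple(_hour_sum(hourly, h) for h in hours)


def _block_hours(d: date, block: str, scheme: DayNightScheme) -> list[pd.Timestamp]:
    base = pd.Timestamp(d)
    if block == "day":
        return [base + pd.Timedelta(hours=h) for h in range(scheme.day_start, scheme.day_end)]
    # night 18:00-05:59 spans midnight and belongs to the date it starts on
    hours = [base + pd.Timedelta(hours=h) for h in range(scheme.day_end, 24)]
    nxt = base + pd.Timedelta(days=1)
    hours += [nxt + pd.Timedelta(hours=h) for h in range(0, scheme.day_start)]
    return hours


def day_scale_series(
    event: TrainingEvent,
    hourly: pd.DataFrame,
    scheme: DayNightScheme = DayNightScheme(),
) -> pd.DataFrame:
    """Day/night mean hourly activity for each labelled day of one event.

    Returns rows ``(event_id, day_label, block, mean_activity, n_hours)``
    where ``mean_activity`` is the mean of the hourly mean indices
    (raw 0-4 scale) over the block's clock hours that have data.  A block
    with no recorded hours is emitted with NaN and ``n_hours`` 0, so that
    pairing can drop it rather than treat it as zero activity.
    """
    labels = label_event_days(event)
    lookup = hourly.dropna(subset=["maa_raw"]).set_index("hour_start")["maa_raw"]
    rows = []
    by_label: dict[DayLabel, list[date]] = {}
    for d, lab in labels.items():
        by_label.setdefault(lab, []).append(d)
    for lab, dates in by_label.items():
        for block in ("day", "night"):
            hours = [h for d in sorted(dates) for h in _block_hours(d, block, scheme)]
            vals = lookup.reindex(hours).dropna()
            rows.append(
                {
                    "event_id": event.event_id,
                    "day_label": lab.value,
                    "block": block,
                    "mean_activity": float(vals.mean()) if len(vals) else np.nan,
                    "n_hours": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def day_scale_table(
    events: list[TrainingEvent],
    hourly: pd.DataFrame,
    scheme: DayNightScheme = DayNightScheme(),
    require_baseline: bool = True,
) -> pd.DataFrame:
    """Day/night means for every (eligible) event, one tidy table.

    With ``require_baseline`` the 3-day clean-baseline rule filters events
    first, mirroring the exclusion of events confounded by a preceding
    exercise.
    """
    keep = [
        ev
        for ev in events
        if not require_baseline or check_baseline_eligibility(ev, events)
    ]
    if not keep:
        return pd.DataFrame(
            columns=["event_id", "day_label", "block", "mean_activity", "n_hours"]
        )
    return pd.concat(
        [day_scale_series(ev, hourly, scheme) for ev in keep], ignore_index=True
    )


def paired_day_values(
    table: pd.DataFrame, label: str, block: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pair day-before means with another day label's means, per event.

    Events missing either member of the pair are dropped (the source of
    the N = 31/30/29 style attrition across labels).  Returns
    ``(before, other)`` arrays aligned by event.
    """
    piv = table[table["block"] == block].pivot_table(
        index="event_id", columns="day_label", values="mean_activity", dropna=False
    )
    if DayLabel.DAY_BEFORE.value not in piv or label not in piv:
        return np.array([]), np.array([])
    sub = piv[[DayLabel.DAY_BEFORE.value, label]].dropna()
    return sub[DayLabel.DAY_BEFORE.value].to_numpy(), sub[label].to_numpy()
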