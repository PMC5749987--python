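"""Ordinal acoustic-activity index and hourly mean activity (MAA).

Each 3-min recording is scored on a 9-level ordinal scale
{0, 1, 1.5, 2, 2.5, 3, 3.5, 4} from the abundance of whistles, burst
pulses (BP) and echolocation clicks: higher values mean more signals and
more signal types.  Hourly mean activity is the arithmetic mean of the
indices of the recordings starting in a clock hour; divided by 4 it is the
MAA response in [0, 1] used by the beta-regression GAM.

Band conventions (chosen so the mapping is a total function): whistle
bands 1-20 / 21-40 / >=41; burst-pulse bands <10 / >=10; click-rate bands
<2 / >=2 clicks per second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SignalCounts",
    "score_recording",
    "score_frame",
    "hourly_mean_activity",
    "INDEX_LEVELS",
]

INDEX_LEVELS = (0.0, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass(frozen=True)
class SignalCounts:
    """Per-recording analyst counts: whistles, burst pulses, click rate (/s)."""

    whistles: int = 0
    burst_pulses: int = 0
    click_rate: float = 0.0

    def __post_init__(self):
        if self.whistles < 0 or self.burst_pulses < 0 or self.click_rate < 0:
            raise ValueError("counts and rates must be nonnegative")

    @property
    def clicks_present(self) -> bool:
        return self.click_rate > 0


def _whistle_band(w: int) -> int:
    """0: none, 1: 1-20, 2: 21-40, 3: >=41."""
    if w == 0:
        return 0
    if w <= 20:
        return 1
    if w <= 40:
        return 2
    return 3


def score_recording(counts: SignalCounts) -> float:
    """Score one recording on the ordinal activity index.

    The logic follows the published index table: the whistle band sets a
    base level and the presence of the other signal types (echolocation,
    burst pulses) raises it; with no whistles, the sub-bands of the click
    rate and burst-pulse count separate the low levels.
    """
    w = _whistle_band(counts.whistles)
    echo = counts.clicks_present
    bp = counts.burst_pulses > 0
    bp_high = counts.burst_pulses >= 10
    click_high = counts.click_rate >= 2.0

    if w == 0:
        if not echo and not bp:
            return 0.0
        if bp and not echo:
            return 1.5 if bp_high else 1.0
        if echo and not bp:
            return 1.5 if click_high else 1.0
        # echolocation and BP together: split on the BP band
        return 2.5 if bp_high else 1.5

    n_extra = int(echo) + int(bp)
    base = {1: 1.0, 2: 1.5, 3: 2.5}[w]
    step = {1: (1.0, 2.0), 2: (1.5, 2.0), 3: (1.0, 1.5)}[w]
    if n_extra == 0:
        return base
    if n_extra == 1:
        return base + step[0]
    return base + step[1]


def score_frame(counts: pd.DataFrame) -> pd.Series:
    """Vectorized activity index for a counts DataFrame.

    Expects columns ``whistles``, ``burst_pulses``, ``click_rate_hz``;
    returns a float Series named ``index`` aligned with the input.
    """
    w = counts["whistles"].to_numpy()
    bp_n = counts["burst_pulses"].to_numpy()
    cr = counts["click_rate_hz"].to_numpy()

    wband = np.select([w == 0, w <= 20, w <= 40], [0, 1, 2], default=3)
    echo = cr > 0
    bp = bp_n > 0
    bp_high = bp_n >= 10
    click_high = cr >= 2.0
    n_extra = echo.astype(int) + bp.astype(int)

    idx = np.zeros(len(counts))
    w0 = wband == 0
    idx[w0 & bp & ~echo] = np.where(bp_high[w0 & bp & ~echo], 1.5, 1.0)
    idx[w0 & echo & ~bp] = np.where(click_high[w0 & echo & ~bp], 1.5, 1.0)
    idx[w0 & echo & bp] = np.where(bp_high[w0 & echo & bp], 2.5, 1.5)

    base = np.choose(wband, [0.0, 1.0, 1.5, 2.5])
    one = np.choose(wband, [0.0, 1.0, 1.5, 1.0])
    two = np.choose(wband, [0.0, 2.0, 2.0, 1.5])
    wpos = wband > 0
    idx[wpos] = (
        base[wpos]
        + np.where(n_extra[wpos] >= 1, one[wpos], 0.0)
        + np.where(n_extra[wpos] == 2, two[wpos] - one[wpos], 0.0)
    )
    return pd.Series(idx, index=counts.index, name="index")


def hourly_mean_activity(
    records: pd.DataFrame, hour_grid: pd.DatetimeIndex | None = None
) -> pd.DataFrame:
    """Aggregate per-recording indices to hourly mean activity.

    ``records`` needs columns ``site_id``, ``start`` and ``index``.  A
    recording belongs to the clock hour its start time falls in.  Returns
    columns ``site_id``, ``hour_start``, ``maa_raw`` (mean index, 0-4),
    ``maa`` (= maa_raw / 4, in [0, 1]) and ``n_segments``.  When an
    ``hour_grid`` is given, hours without recordings are emitted with NaN
    activity (never zero: index 0 is a real observation, absence is not).
    """
    df = records.copy()
    df["hour_start"] = df["start"].dt.floor("h")
    grouped = (
        df.groupby(["site_id", "hour_start"], as_index=False)
        .agg(maa_raw=("index", "mean"), n_segments=("index", "size"))
    )
    if hour_grid is not None:
        full = pd.MultiIndex.from_product(
            [grouped["site_id"].unique(), hour_grid], names=["site_id", "hour_start"]
        )
        grouped = (
            grouped.set_index(["site_id", "hour_start"])
            .reindex(full)
            .reset_index()
        )
        grouped["n_segments"] = grouped["n_segments"].fillna(0).astype(int)
    grouped["maa"] = grouped["maa_raw"] / 4.0
    return grouped
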