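"""Daily/monthly occurrence summaries.

A *detection* is a 3-min recording containing any dolphin signal, i.e. an
activity index above 0.  Daily detection counts, monthly means (pooled
across years) with standard deviations, and the percentage of monitored
days with at least one detection summarise occurrence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "daily_detections",
    "monthly_summary",
    "percent_days_present",
    "recording_hours",
    "plot_monthly",
]


def daily_detections(records: pd.DataFrame) -> pd.DataFrame:
    """Per site-date detection counts.

    ``records`` needs columns ``site_id``, ``start``, ``index``.  Returns
    ``site_id``, ``date``, ``n_detections`` (recordings with index > 0)
    and ``n_recordings_monitored``.
    """
    df = records.copy()
    df["date"] = df["start"].dt.date
    out = df.groupby(["site_id", "date"], as_index=False).agg(
        n_detections=("index", lambda s: int((s > 0).sum())),
        n_recordings_monitored=("index", "size"),
    )
    return out


def monthly_summary(dailies: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample sd of daily detections per month, pooled across years.

    A month observed on a single day gets a missing sd (NaN), never 0.
    """
    df = dailies.copy()
    df["month"] = pd.to_datetime(df["date"]).dt.month
    out = df.groupby("month", as_index=False).agg(
        mean_detections=("n_detections", "mean"),
        sd_detections=("n_detections", lambda s: s.std(ddof=1) if len(s) > 1 else np.nan),
        n_days=("n_detections", "size"),
    )
    return out


def percent_days_present(dailies: pd.DataFrame) -> float:
    """Percentage of monitored days with at least one detection."""
    if len(dailies) == 0:
        raise ValueError("need at least one monitored day")
    return 100.0 * float((dailies["n_detections"] > 0).mean())


def recording_hours(n_recordings: int, duration_s: float = 180.0) -> int:
    """Total recorded hours for a number of fixed-length recordings, to the nearest hour."""
    if n_recordings < 0:
        raise ValueError("n_recordings must be >= 0")
    return int(round(n_recordings * duration_s / 3600.0))


def plot_monthly(summary: pd.DataFrame, path) -> None:
    """Bar plot of monthly mean daily detections with sd error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(
        summary["month"],
        summary["mean_detections"],
        yerr=summary["sd_detections"].fillna(0.0),
        color="steelblue",
        capsize=3,
    )
    ax.set_xlabel("month")
    ax.set_ylabel("mean daily detections")
    ax.set_xticks(range(1, 13))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
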