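"""Synthetic acoustic scenes: duty-cycled schedules, signal counts, waveforms.

The generator emulates the structure of a coastal dolphin monitoring study:
bottom-moored recorders sample 3 minutes out of every 6 (a 50% duty cycle),
dolphin signalling shows diel and seasonal variation, and detonations are
followed by a daytime suppression of acoustic activity with a rebound on
the second day after the event.  Everything downstream of the analyst
(activity indexing, event windows, paired tests, GAM) can therefore be
exercised end-to-end without any real recordings.

Randomness: one integer seed drives everything; independent substreams are
derived with :class:`numpy.random.SeedSequence` spawning so that, e.g.,
count simulation and waveform synthesis never share draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import TrainingEvent

__all__ = [
    "DutyCycle",
    "ActivityModelParams",
    "WaveformSpec",
    "build_recording_schedule",
    "simulate_counts",
    "synthesize_waveform",
]

#: substream indices for seed splitting (documented contract)
_STREAM_COUNTS = 0
_STREAM_WAVEFORM = 1


@dataclass(frozen=True)
class DutyCycle:
    """Recorder duty cycle: ``on_duration`` seconds out of every ``cycle_period``."""

    on_duration: float = 180.0
    cycle_period: float = 360.0
    offset: float = 0.0

    def __post_init__(self):
        if not (0 < self.on_duration <= self.cycle_period):
            raise ValueError("require 0 < on_duration <= cycle_period")
        if not (0 <= self.offset < self.cycle_period):
            raise ValueError("offset must lie in [0, cycle_period)")

    @property
    def coverage(self) -> float:
        return self.on_duration / self.cycle_period


def _default_diel_curve() -> np.ndarray:
    # Elevated night rates plus a midday peak (qualitative baseline diel shape).
    curve = np.ones(24)
    curve[0:6] = 1.3
    curve[6:10] = 0.7
    curve[10:13] = 1.4  # midday activity peak around 11:00-12:00
    curve[13:18] = 0.8
    curve[18:20] = 1.0
    curve[20:24] = 1.3
    return curve


def _default_seasonal_curve() -> np.ndarray:
    # Month multipliers (Jan..Dec): October peak, February trough at 10% of peak.
    return np.array(
        [0.20, 0.10, 0.30, 0.60, 0.80, 0.90, 0.95, 1.00, 0.95, 1.00, 0.50, 0.30]
    )


@dataclass
class ActivityModelParams:
    """Parameters of the synthetic dolphin-signalling model.

    A dolphin group is present in a given 3-min recording with a Bernoulli
    probability (day/night base probability times the month's seasonal
    multiplier).  Given presence, whistle and burst-pulse counts are
    negative binomial and the echolocation click rate is gamma distributed.
    After a detonation, daytime presence is multiplied by ``suppression``
    (animals leave the area); on the second day after the event daytime
    presence is multiplied by ``rebound``.
    """

    base_rate: float = 15.0           # mean whistles per recording given presence
    presence_prob_day: float = 0.35
    presence_prob_night: float = 0.50
    diel_curve: np.ndarray = field(default_factory=_default_diel_curve)
    seasonal_curve: np.ndarray = field(default_factory=_default_seasonal_curve)
    bp_rate: float = 3.0              # mean burst pulses per recording given presence
    click_rate_scale: float = 1.5     # mean clicks/s given presence and clicking
    click_prob: float = 0.7           # P(click train | presence)
    suppression: float = 0.4          # presence multiplier in post-blast daytime windows
    suppression_hours: float = 12.0   # max daytime window length after a day's first UNDET
    rebound: float = 1.3              # presence multiplier on second day after the event
    dispersion: float = 2.0           # NB size parameter k (var = mu + mu^2/k)
    day_start_hour: int = 6           # daytime block 06:00-17:59
    day_end_hour: int = 18
    seed: int = 0

    def validate(self) -> None:
        arrays_ok = (
            len(self.diel_curve) == 24
            and len(self.seasonal_curve) == 12
            and np.all(np.asarray(self.diel_curve) > 0)
            and np.all(np.asarray(self.seasonal_curve) > 0)
        )
        if not arrays_ok:
            raise ValueError("diel_curve (24) and seasonal_curve (12) must be strictly positive")
        if min(self.base_rate, self.bp_rate, self.click_rate_scale) < 0:
            raise ValueError("rates must be nonnegative")
        if not (0 <= self.suppression <= 1 <= self.rebound):
            raise ValueError("require suppression <= 1 <= rebound")
        if not (0 <= self.presence_prob_day <= 1 and 0 <= self.presence_prob_night <= 1):
            raise ValueError("presence probabilities must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


@dataclass(frozen=True)
class WaveformSpec:
    """Specification of a rendered test waveform.

    Levels are in dB: ``ambient_level`` re full scale (so -40 means the
    ambient RMS is 1% of full scale) and ``transient_peak_level`` above
    ambient.  The transient is a broadband noise burst with a near
    instantaneous rise (<= 1 ms) followed by exponentially decaying
    reverberation with amplitude time constant ``reverb_time_constant``.
    """

    sample_rate: float = 50_000.0
    duration: float = 180.0
    ambient_level: float = -40.0
    transient_onset: float | None = None
    transient_peak_level: float = 30.0
    reverb_time_constant: float = 1.0
    rise_time: float = 0.5e-3

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.transient_onset is not None:
            if not (0 <= self.transient_onset < self.duration):
                raise ValueError("transient_onset must lie in [0, duration)")
            if self.transient_peak_level <= 0:
                raise ValueError("transient_peak_level must be > 0 when a transient is requested")
            if self.rise_time > 1e-3:
                raise ValueError("rise_time must be <= 1 ms (near instantaneous)")


def build_recording_schedule(
    start, end, duty: DutyCycle = DutyCycle(), site_id: str = "B"
) -> pd.DataFrame:
    """Build the duty-cycled recording schedule for ``[start, end)``.

    Segments start at ``start + offset + k * cycle_period`` and last
    ``on_duration`` seconds; only segments starting before ``end`` are kept.
    Returns a DataFrame with columns ``site_id``, ``start``, ``duration_s``.
    """
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if end <= start:
        raise ValueError("end must be after start")
    first = start + pd.Timedelta(seconds=duty.offset)
    starts = pd.date_range(
        first, end - pd.Timedelta(nanoseconds=1), freq=pd.Timedelta(seconds=duty.cycle_period)
    )
    return pd.DataFrame(
        {
            "site_id": site_id,
            "start": starts,
            "duration_s": duty.on_duration,
        }
    )


def _suppression_multiplier(
    schedule: pd.DataFrame, params: ActivityModelParams, events: list[TrainingEvent]
) -> np.ndarray:
    """Per-segment presence multiplier encoding suppression and rebound.

    Daytime segments are suppressed (i) on each UNDET day, from that day's
    first UNDET for up to ``suppression_hours``, and (ii) on the whole day
    after the last UNDET of the event.  Daytime segments on the second day
    after the last UNDET get the rebound multiplier.  Night segments are
    unaffected: the study observed activity returning to baseline at night.
    """
    starts = schedule["start"]
    dates = starts.dt.normalize().to_numpy()
    hours = starts.dt.hour.to_numpy()
    is_day = (hours >= params.day_start_hour) & (hours < params.day_end_hour)
    mult = np.ones(len(schedule))
    for ev in events:
        for d in ev.undet_days:
            first_t = min(u.onset_time for u in ev.undets if u.day == d)
            sel = (
                is_day
                & (dates == np.datetime64(pd.Timestamp(d)))
                & (starts.to_numpy() >= np.datetime64(first_t))
                & (
                    starts.to_numpy()
                    < np.datetime64(first_t + pd.Timedelta(hours=params.suppression_hours))
                )
            )
            mult[sel] = np.minimum(mult[sel], params.suppression)
        after = np.datetime64(pd.Timestamp(ev.last_undet_day) + pd.Timedelta(days=1))
        second = np.datetime64(pd.Timestamp(ev.last_undet_day) + pd.Timedelta(days=2))
        mult[is_day & (dates == after)] = np.minimum(
            mult[is_day & (dates == after)], params.suppression
        )
        sel2 = is_day & (dates == second) & (mult == 1.0)
        mult[sel2] = params.rebound
    return mult


def simulate_counts(
    schedule: pd.DataFrame,
    params: ActivityModelParams,
    events: list[TrainingEvent] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate per-recording signal counts on a schedule.

    Returns the schedule with added columns ``whistles``, ``burst_pulses``
    and ``click_rate_hz``.  Fully reproducible for a fixed
    ``params.seed`` (or an explicitly supplied generator).
    """
    params.validate()
    if rng is None:
        root = np.random.SeedSequence(params.seed)
        rng = np.random.default_rng(root.spawn(_STREAM_COUNTS + 1)[_STREAM_COUNTS])
    out = schedule.copy()
    n = len(schedule)
    if n == 0:
        for c in ("whistles", "burst_pulses", "click_rate_hz"):
            out[c] = np.array([], dtype=float)
        return out

    starts = schedule["start"]
    hours = starts.dt.hour.to_numpy()
    months = starts.dt.month.to_numpy()
    diel = np.asarray(params.diel_curve, dtype=float)[hours]
    seasonal = np.asarray(params.seasonal_curve, dtype=float)[months - 1]
    is_day = (hours >= params.day_start_hour) & (hours < params.day_end_hour)

    p_base = np.where(is_day, params.presence_prob_day, params.presence_prob_night)
    mult = _suppression_multiplier(schedule, params, events or [])
    p = np.clip(p_base * seasonal * mult, 0.0, 1.0)
    present = rng.random(n) < p

    rate_mod = diel  # conditional signal rates carry the diel shape
    k = params.dispersion

    def nb(mean: np.ndarray) -> np.ndarray:
        mean = np.maximum(mean, 1e-12)
        return rng.negative_binomial(k, k / (k + mean))

    whistles = np.where(present, nb(params.base_rate * rate_mod), 0)
    bp = np.where(present, nb(params.bp_rate * rate_mod), 0)
    clicking = present & (rng.random(n) < params.click_prob)
    click_rate = np.where(
        clicking,
        rng.gamma(2.0, np.maximum(params.click_rate_scale * rate_mod, 1e-12) / 2.0),
        0.0,
    )

    out["whistles"] = whistles.astype(int)
    out["burst_pulses"] = bp.astype(int)
    out["click_rate_hz"] = click_rate
    return out


def synthesize_waveform(
    spec: WaveformSpec, seed: int = 0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render a waveform: Gaussian ambient noise plus an optional transient.

    The transient is white noise under an amplitude envelope that rises
    linearly over ``rise_time`` and decays as ``exp(-t/tau)``; its peak RMS
    sits ``transient_peak_level`` dB above the ambient RMS.  Deterministic
    for a fixed seed.  Returns a float array in [-1, 1] nominal full scale.
    """
    if rng is None:
        root = np.random.SeedSequence(seed)
        rng = np.random.default_rng(root.spawn(_STREAM_WAVEFORM + 1)[_STREAM_WAVEFORM])
    n = int(round(spec.duration * spec.sample_rate))
    sigma = 10.0 ** (spec.ambient_level / 20.0)
    x = rng.normal(0.0, sigma, n)
    if spec.transient_onset is not None:
        t = np.arange(n) / spec.sample_rate - spec.transient_onset
        peak = sigma * 10.0 ** (spec.transient_peak_level / 20.0)
        env = np.zeros(n)
        rising = (t >= 0) & (t < spec.rise_time)
        env[rising] = peak * t[rising] / spec.rise_time
        decaying = t >= spec.rise_time
        env[decaying] = peak * np.exp(-(t[decaying] - spec.rise_time) / spec.reverb_time_constant)
        x = x + env * rng.normal(0.0, 1.0, n)
    return x


def write_wav(path, waveform: np.ndarray, sample_rate: float) -> None:
    """Write a waveform as 16-bit PCM WAV (clipping at full scale)."""
    from scipy.io import wavfile

    clipped = np.clip(waveform, -1.0, 1.0)
    wavfile.write(path, int(sample_rate), (clipped * 32767).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a PCM WAV as a float array in [-1, 1] plus the sample rate."""
    from scipy.io import wavfile

    sr, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data / 32768.0
    elif data.dtype == np.int32:
        data = data / 2147483648.0
    elif data.dtype == np.uint8:
        data = (data.astype(float) - 128) / 128.0
    return data.astype(float), float(sr)
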