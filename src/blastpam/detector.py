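"""Impulsive-transient (detonation) detection in hydrophone recordings.

The detector works on a short-window RMS envelope.  A running background
level is estimated as the median envelope over the preceding background
window; an event is triggered where the envelope exceeds the background by
a threshold *and* rose from background + 6 dB to its peak within a short
rise time — the rise-time gate rejects ship passages and other slowly
swelling noise.  The reverberation duration is the time from onset until
the envelope stays below background + 6 dB, and drives the small / medium
/ large size classing.

All thresholds are relative to the background estimate, so detections are
invariant to a constant gain applied to the whole recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import UndetEvent, classify_size

__all__ = ["DetectorConfig", "detect_transients", "measure_reverb_duration"]


@dataclass(frozen=True)
class DetectorConfig:
    rms_window: float = 0.010          # s; envelope frame length
    background_window: float = 30.0    # s; running-median window
    trigger_threshold: float = 20.0    # dB above background
    max_rise_time: float = 0.050       # s; +6 dB crossing to peak
    end_threshold: float = 6.0         # dB above background; reverb end criterion
    end_sustain: float = 0.050         # s the envelope must stay below threshold
    refractory: float = 5.0            # s; events closer than this are merged

    def __post_init__(self):
        if self.rms_window <= 0 or self.background_window <= 0:
            raise ValueError("windows must be positive")
        if self.rms_window * 10 > self.background_window:
            raise ValueError("rms_window must be much shorter than background_window")
        if self.trigger_threshold <= self.end_threshold:
            raise ValueError("trigger_threshold must exceed end_threshold")
        if self.refractory <= 0:
            raise ValueError("refractory must be > 0")


def _rms_envelope(waveform: np.ndarray, sample_rate: float, cfg: DetectorConfig):
    """Non-overlapping frame RMS envelope and the frame duration in s."""
    frame = max(1, int(round(cfg.rms_window * sample_rate)))
    n_frames = len(waveform) // frame
    if n_frames == 0:
        raise ValueError("waveform shorter than one RMS frame")
    x = waveform[: n_frames * frame].reshape(n_frames, frame)
    env = np.sqrt(np.mean(x * x, axis=1))
    return env, frame / sample_rate


def _running_background(env: np.ndarray, frame_dt: float, cfg: DetectorConfig) -> np.ndarray:
    """Median of the preceding ``background_window`` of envelope frames.

    The window excludes the current frame, so a transient does not inflate
    its own background estimate; the median keeps the estimate robust while
    reverberation from a previous event is still decaying.
    """
    w = max(2, int(round(cfg.background_window / frame_dt)))
    s = pd.Series(env).shift(1)
    bg = s.rolling(window=w, min_periods=max(2, w // 4)).median().to_numpy()
    # frames without enough history fall back to the first valid estimate
    first_valid = np.flatnonzero(~np.isnan(bg))
    if len(first_valid) == 0:
        raise ValueError("waveform provides no background context")
    bg[: first_valid[0]] = bg[first_valid[0]]
    return bg


def detect_transients(
    waveform: np.ndarray,
    sample_rate: float,
    cfg: DetectorConfig = DetectorConfig(),
    t0: pd.Timestamp | None = None,
) -> list[UndetEvent]:
    """Detect detonation-like transients in a waveform.

    Returns one :class:`UndetEvent` per detection with onset time (seconds
    from the start of the recording, or an absolute timestamp when ``t0``
    is given), peak level in dB above background, measured reverberation
    duration, censoring flag and size class.
    """
    waveform = np.asarray(waveform, dtype=float)
    if len(waveform) / sample_rate < cfg.background_window:
        raise ValueError("waveform shorter than background_window: insufficient context")
    env, frame_dt = _rms_envelope(waveform, sample_rate, cfg)
    bg = _running_background(env, frame_dt, cfg)

    eps = np.finfo(float).tiny
    rel_db = 20.0 * np.log10(np.maximum(env, eps) / np.maximum(bg, eps))
    hot = rel_db >= cfg.trigger_threshold

    max_rise_frames = max(1, int(round(cfg.max_rise_time / frame_dt)))
    refractory_frames = max(1, int(round(cfg.refractory / frame_dt)))

    events: list[UndetEvent] = []
    last_end = -refractory_frames
    i = 0
    n = len(env)
    while i < n:
        if not hot[i]:
            i += 1
            continue
        trigger = i
        bg_here = bg[trigger]
        # onset: walk back to the last frame at or below background + 6 dB
        onset = trigger
        floor_db = cfg.end_threshold
        while onset > 0 and 20.0 * np.log10(max(env[onset - 1], eps) / max(bg_here, eps)) > floor_db:
            onset -= 1
        # contiguous hot run and its peak
        j = trigger
        while j + 1 < n and hot[j + 1]:
            j += 1
        peak_idx = onset + int(np.argmax(env[onset : j + 1]))
        peak_db = 20.0 * np.log10(max(env[peak_idx], eps) / max(bg_here, eps))
        # rise time: from the +6 dB crossing to first reaching the trigger
        # level (robust to RMS fluctuations moving the argmax within the
        # decaying reverberation)
        rise_frames = trigger - onset
        if rise_frames <= max_rise_frames:
            if events and (onset - last_end) < refractory_frames:
                pass  # merged into the previous event
            else:
                duration, censored = _reverb_from_envelope(
                    env, frame_dt, onset, bg_here, cfg
                )
                onset_s = onset * frame_dt
                onset_time = (
                    t0 + pd.Timedelta(seconds=onset_s)
                    if t0 is not None
                    else pd.Timestamp(0) + pd.Timedelta(seconds=onset_s)
                )
                events.append(
                    UndetEvent(
                        onset_time=onset_time,
                        peak_level=float(peak_db),
                        reverb_duration=float(duration),
                        censored=censored,
                    )
                )
        last_end = j
        i = j + 1
    return events


def _reverb_from_envelope(env, frame_dt, onset, background, cfg):
    """Duration from onset until the envelope stays below background + 6 dB.

    Requires the envelope to remain below the threshold for at least
    ``end_sustain`` seconds; if it never does before the recording ends the
    duration is right-censored at the end of the recording.
    """
    thr = background * 10.0 ** (cfg.end_threshold / 20.0)
    sustain = max(1, int(round(cfg.end_sustain / frame_dt)))
    # light smoothing so single-frame RMS fluctuations near the threshold
    # do not delay (or trigger early) the end-of-reverberation decision
    tail = env[onset:]
    if len(tail) >= 3:
        sm = np.convolve(tail, np.ones(3) / 3.0, mode="same")
        sm[0], sm[-1] = tail[0], tail[-1]
    else:
        sm = tail
    below = sm < thr
    n = len(below)
    run = 0
    for idx in range(n):
        run = run + 1 if below[idx] else 0
        if run >= sustain:
            end = idx - sustain + 1  # first frame of the sustained quiet run
            return end * frame_dt, False
    return n * frame_dt, True


def measure_reverb_duration(
    waveform: np.ndarray,
    sample_rate: float,
    onset: float,
    cfg: DetectorConfig = DetectorConfig(),
) -> tuple[float, bool]:
    """Measure reverberation duration for a known onset (s into the recording).

    The background is the median envelope over the ``background_window``
    preceding the onset (frozen, so the reverberation itself cannot
    contaminate it).  Returns ``(duration_s, censored)``.
    """
    waveform = np.asarray(waveform, dtype=float)
    env, frame_dt = _rms_envelope(waveform, sample_rate, cfg)
    onset_idx = int(round(onset / frame_dt))
    bg_frames = int(round(cfg.background_window / frame_dt))
    lo = max(0, onset_idx - bg_frames)
    if onset_idx - lo < 2:
        raise ValueError("need background context before the onset")
    background = float(np.median(env[lo:onset_idx]))
    return _reverb_from_envelope(env, frame_dt, onset_idx, background, cfg)


def size_class_of(duration: float) -> str:
    """Convenience re-export of the size classing used by the detector."""
    return classify_size(duration)
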