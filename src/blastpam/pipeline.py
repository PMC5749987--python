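"""End-to-end pipeline orchestration and deterministic fixture generation.

Stages: simulate (schedule + counts + optional waveforms) -> detect ->
score -> windows -> test -> gam -> sel.  Plain CSV (and WAV) files are the
interchange surface between stages so each stage can be run and inspected
on its own; a JSON manifest records the seed, resolved configuration and
per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import hourly_mean_activity, score_frame
from .detector import DetectorConfig, detect_transients
from .events import TrainingEvent, UndetEvent
from .gam import BetaGAM, all_subsets_selection, boundary_transform
from .occurrence import daily_detections, monthly_summary, percent_days_present
from .propagation import scenario_table
from .scene import (
    ActivityModelParams,
    DutyCycle,
    WaveformSpec,
    build_recording_schedule,
    simulate_counts,
    synthesize_waveform,
    write_wav,
)
from .stats import PairedSample, compare_paired, wilcoxon_signed_rank
from .windows import day_scale_table, paired_day_values

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "demo_events"]

STAGES = ("simulate", "detect", "score", "windows", "test", "gam", "sel")


@dataclass
class RunConfig:
    """Resolved pipeline configuration (one simulated site)."""

    stages: tuple[str, ...] = STAGES
    start: str = "2013-01-01"
    end: str = "2014-01-01"
    site_id: str = "B"
    n_events: int = 31
    event_hour: int = 10          # most detonations fall between 10:00 and 17:59
    duty: DutyCycle = field(default_factory=DutyCycle)
    params: ActivityModelParams = field(default_factory=ActivityModelParams)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    n_demo_waveforms: int = 0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "duty" in d:
            d["duty"] = DutyCycle(**d["duty"])
        if "params" in d:
            p = dict(d["params"])
            for key in ("diel_curve", "seasonal_curve"):
                if key in p:
                    p[key] = np.asarray(p[key], dtype=float)
            d["params"] = ActivityModelParams(**p)
        if "detector" in d:
            d["detector"] = DetectorConfig(**d["detector"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def demo_events(config: RunConfig) -> list[TrainingEvent]:
    """Evenly spaced single-day training events across the configured span."""
    start = pd.Timestamp(config.start)
    end = pd.Timestamp(config.end)
    n_days = (end - start).days
    if config.n_events == 0:
        return []
    spacing = max(5, n_days // max(config.n_events, 1))
    events = []
    for i in range(config.n_events):
        day = start + pd.Timedelta(days=3 + i * spacing)
        if day >= end - pd.Timedelta(days=3):
            break
        onset = day + pd.Timedelta(hours=config.event_hour, minutes=5)
        events.append(
            TrainingEvent(
                event_id=i + 1,
                undets=[UndetEvent(onset_time=onset, peak_level=30.0,
                                   reverb_duration=4.0)],
            )
        )
    return events


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(_jsonable(asdict(config)), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the enabled stages; returns the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": _jsonable(asdict(config)),
        "stages": {},
    }
    config.params.seed = config.seed
    events = demo_events(config)
    counts = hourly = day_table = None
    try:
        if "simulate" in config.stages:
            schedule = build_recording_schedule(
                config.start, config.end, config.duty, site_id=config.site_id
            )
            counts = simulate_counts(schedule, config.params, events)
            counts_out = counts.copy()
            counts_out["start_iso8601"] = counts_out["start"].dt.strftime(
                "%Y-%m-%dT%H:%M:%S"
            )
            counts_out[
                ["site_id", "start_iso8601", "duration_s", "whistles",
                 "burst_pulses", "click_rate_hz"]
            ].to_csv(out / "counts.csv", index=False)
            manifest["stages"]["simulate"] = {"rows": int(len(counts))}
            if config.n_demo_waveforms > 0:
                wav_dir = out / "waveforms"
                wav_dir.mkdir(exist_ok=True)
                for i in range(config.n_demo_waveforms):
                    spec = WaveformSpec(
                        sample_rate=4000.0, duration=60.0, transient_onset=30.0,
                        transient_peak_level=30.0,
                        reverb_time_constant=[0.3, 1.5, 3.0][i % 3],
                    )
                    write_wav(
                        wav_dir / f"wave_{i:02d}.wav",
                        synthesize_waveform(spec, seed=config.seed + i),
                        spec.sample_rate,
                    )
                manifest["stages"]["simulate"]["waveforms"] = config.n_demo_waveforms

        if "detect" in config.stages:
            wav_dir = out / "waveforms"
            rows = []
            if wav_dir.exists():
                from .scene import read_wav

                cfg = DetectorConfig(
                    background_window=20.0, refractory=2.0
                ) if config.detector == DetectorConfig() else config.detector
                for wav in sorted(wav_dir.glob("*.wav")):
                    data, sr = read_wav(wav)
                    for ev in detect_transients(data, sr, cfg):
                        rows.append(
                            {
                                "file": wav.name,
                                "event_time_iso8601": ev.onset_time.isoformat(),
                                "peak_db": ev.peak_level,
                                "reverb_s": ev.reverb_duration,
                                "censored": ev.censored,
                                "size_class": ev.size_class,
                            }
                        )
            pd.DataFrame(
                rows,
                columns=["file", "event_time_iso8601", "peak_db", "reverb_s",
                         "censored", "size_class"],
            ).to_csv(out / "detections.csv", index=False)
            manifest["stages"]["detect"] = {"rows": len(rows)}

        if "score" in config.stages and counts is not None:
            scored = counts.copy()
            scored["index"] = score_frame(counts)
            scored_out = scored.copy()
            scored_out["start_iso8601"] = scored_out["start"].dt.strftime(
                "%Y-%m-%dT%H:%M:%S"
            )
            scored_out[["site_id", "start_iso8601", "index"]].assign(
                index=lambda d: d["index"].map(lambda v: f"{v:.1f}")
            ).to_csv(out / "activity.csv", index=False)
            hourly = hourly_mean_activity(scored)
            hourly.to_csv(out / "hourly.csv", index=False)
            dailies = daily_detections(scored)
            monthly_summary(dailies).to_csv(out / "monthly.csv", index=False)
            manifest["stages"]["score"] = {
                "rows": int(len(scored)),
                "hours": int(len(hourly)),
                "percent_days_present": percent_days_present(dailies),
            }

        if "windows" in config.stages and hourly is not None:
            day_table = day_scale_table(events, hourly)
            day_table.to_csv(out / "day_windows.csv", index=False)
            manifest["stages"]["windows"] = {"rows": int(len(day_table))}

        if "test" in config.stages and day_table is not None:
            results = []
            for label in ("day_of", "day_after", "second_day_after"):
                for block in ("day", "night"):
                    before, other = paired_day_values(day_table, label, block)
                    if len(before) < 5:
                        continue
                    res = compare_paired(
                        PairedSample(before, other, labels=("day_before", label))
                    )
                    results.append(
                        {
                            "comparison_id": f"{label}_{block}",
                            "test": res.test,
                            "statistic": res.statistic,
                            "df": res.df,
                            "p": res.p_value,
                            "effect_size": res.effect_size,
                            "convention": res.convention,
                            "n": res.n,
                        }
                    )
            pd.DataFrame(results).to_csv(out / "tests.csv", index=False)
            manifest["stages"]["test"] = {"rows": len(results)}

        if "gam" in config.stages and hourly is not None:
            gdf = hourly.dropna(subset=["maa_raw"]).copy()
            gdf["hour_of_day"] = gdf["hour_start"].dt.hour
            month = gdf["hour_start"].dt.month
            gdf["season"] = pd.cut(
                month, bins=[0, 2, 5, 8, 11, 12],
                labels=["winter", "spring", "summer", "autumn", "winter2"],
            ).astype(str).str.replace("winter2", "winter")
            y = boundary_transform(gdf["maa"].to_numpy())
            table = all_subsets_selection(
                gdf, y,
                candidate_terms=[("s", "hour_of_day"), ("factor", "season")],
                lambda_grid=(0.1, 1.0, 10.0, 100.0),
            )
            table.to_csv(out / "model_selection.csv", index=False)
            manifest["stages"]["gam"] = {
                "rows": int(len(table)),
                "selected": table.loc[table["selected"], "predictors"].iloc[0],
            }

        if "sel" in config.stages:
            tab = scenario_table()
            tab.to_csv(out / "sel_scenarios.csv", index=False)
            manifest["stages"]["sel"] = {"rows": int(len(tab))}
    except Exception as exc:  # preserve partial outputs + machine-readable error
        manifest["error"] = {"stage": "unknown", "message": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


FIXTURE_KINDS = ("waveforms", "counts", "events", "gam")


def make_fixtures(kind: str, seed: int, out_dir) -> list[Path]:
    """Write small deterministic fixtures used by the test suite and demos."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "waveforms":
        # reverberation time constants chosen so the measured durations land
        # in the three size classes (about 1, 5 and 8 s)
        for i, tau in enumerate([0.35, 1.8, 2.9]):
            spec = WaveformSpec(
                sample_rate=4000.0, duration=60.0, transient_onset=25.0,
                transient_peak_level=30.0, reverb_time_constant=tau,
            )
            p = out / f"transient_{i}.wav"
            write_wav(p, synthesize_waveform(spec, seed=seed + i), spec.sample_rate)
            written.append(p)
    elif kind == "counts":
        cfg = RunConfig(start="2013-06-01", end="2013-06-05", n_events=1,
                        seed=seed)
        schedule = build_recording_schedule(cfg.start, cfg.end, cfg.duty)
        cfg.params.seed = seed
        counts = simulate_counts(schedule, cfg.params, demo_events(cfg))
        p = out / "counts_4day.csv"
        counts.assign(
            start_iso8601=counts["start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        )[["site_id", "start_iso8601", "duration_s", "whistles", "burst_pulses",
           "click_rate_hz"]].to_csv(p, index=False)
        written.append(p)
    elif kind == "events":
        single = TrainingEvent(
            event_id=1,
            undets=[UndetEvent(onset_time="2013-06-10 11:00", reverb_duration=1.0)],
        )
        multi = TrainingEvent(
            event_id=2,
            undets=[
                UndetEvent(onset_time=f"2013-07-{d} 10:30", reverb_duration=8.0)
                for d in (10, 11, 12)
            ],
        )
        rows = [
            {"event_id": ev.event_id, "onset": u.onset_time.isoformat(),
             "reverb_s": u.reverb_duration, "size_class": u.size_class}
            for ev in (single, multi)
            for u in ev.undets
        ]
        p = out / "training_events.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)
    elif kind == "gam":
        rng = np.random.default_rng(seed)
        n = 2000
        hour = rng.integers(0, 24, n)
        day = rng.choice(["day_before", "day_of", "day_after", "second_day_after"], n)
        eta = (
            -0.5
            + 0.8 * np.cos(2 * np.pi * (hour - 2) / 24.0)
            + pd.Series(day).map(
                {"day_before": 0.0, "day_of": -0.6, "day_after": -0.4,
                 "second_day_after": 0.2}
            ).to_numpy()
        )
        mu = 1.0 / (1.0 + np.exp(-eta))
        phi = 20.0
        y = rng.beta(mu * phi, (1 - mu) * phi)
        df = pd.DataFrame({"hour_of_day": hour, "day": day, "maa": y})
        p = out / "gam_sim.csv"
        df.to_csv(p, index=False)
        meta = out / "gam_sim_params.json"
        with open(meta, "w") as fh:
            json.dump({"phi": phi, "seed": seed, "n": n,
                       "day_effects": {"day_before": 0.0, "day_of": -0.6,
                                       "day_after": -0.4, "second_day_after": 0.2}},
                      fh, indent=2)
        written += [p, meta]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    return written
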