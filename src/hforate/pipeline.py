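"""End-to-end orchestration: simulate -> detect -> rates -> features ->
label -> train -> evaluate, with one config, one master seed, structured
JSONL logging, and content-keyed stage caching."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .core import ChannelMap, HFOEvent
from .detect import DetectorConfig, common_average_reference, \
    pseudo_prospective_detect, redact_artifacts
from .evaluation import ALPHA, AUC_THRESHOLD, summarize_patient
from .labeling import apply_data_gap_exclusions, label_windows
from .model import MIN_PREICTAL, run_patient
from .rates import FeatureWindowConfig, build_feature_matrix, compute_chfo_rate
from .synthetic import PreictalEffect, SeizureSchedule, SimConfig, \
    generate_seizure_schedule, make_channel_map, simulate_event_stream, \
    synthesize_ieeg

__all__ = [
    "RunConfig",
    "run_all",
    "validate_inputs",
    "validate_patient",
    "schedule_model_fits",
    "simulate_patient_observations",
]

WINDOW_LENGTHS = (30, 15, 10)


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    out_dir: str = "run"
    n_seizures: int = 8
    recording_duration_s: float = 24 * 3600.0
    min_seizure_gap_s: float = 7200.0
    sim: SimConfig = field(default_factory=SimConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    window_lengths: tuple[int, ...] = WINDOW_LENGTHS
    n_repeats: int = 10
    n_perm: int = 1000
    auc_threshold: float = AUC_THRESHOLD
    alpha: float = ALPHA
    master_seed: int = 0
    synthesize_signal: bool = False

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "sim" in d:
            if "preictal_effect" in d["sim"]:
                d["sim"]["preictal_effect"] = PreictalEffect(
                    **d["sim"]["preictal_effect"])
            if d["sim"].get("out_effect"):
                d["sim"]["out_effect"] = PreictalEffect(**d["sim"]["out_effect"])
            d["sim"] = SimConfig(**d["sim"])
        if "detector" in d:
            d["detector"]["band"] = tuple(d["detector"]["band"])
            d["detector"] = DetectorConfig(**d["detector"])
        if "window_lengths" in d:
            d["window_lengths"] = tuple(d["window_lengths"])
        return cls(**d)


def _config_hash(*parts) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(parts, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _Run:
    """Stage bookkeeping: JSONL log plus content-keyed caching."""

    def __init__(self, out_dir: Path):
        self.dir = out_dir
        self.dir.mkdir(parents=True, exist_ok=True)
        self.log_path = self.dir / "run.log.jsonl"

    def log(self, stage: str, **info) -> None:
        rec = {"stage": stage, **info}
        with open(self.log_path, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")

    def cached(self, stage: str, key: str, outputs: list[Path]) -> bool:
        key_file = self.dir / f"{stage}.key"
        if key_file.exists() and key_file.read_text() == key:
            return all(p.exists() for p in outputs)
        return False

    def commit(self, stage: str, key: str) -> None:
        (self.dir / f"{stage}.key").write_text(key)


def validate_patient(
    schedule: SeizureSchedule,
    events: list[HFOEvent],
    min_seizures: int = MIN_PREICTAL,
    min_hours: float = 24.0,
) -> dict:
    """Apply the cohort inclusion criteria to one patient's data.

    A seizure is usable when at least one HFO occurs in its 31-min preictal
    zone; a patient is included with >= ``min_seizures`` usable seizures and
    >= ``min_hours`` of recording.
    """
    reasons = []
    hours = schedule.recording_duration / 3600.0
    if hours < min_hours:
        reasons.append(f"less than {min_hours:g} h of data ({hours:.1f} h)")
    starts = np.sort([e.start_s for e in events])
    usable = 0
    for onset in schedule.onsets:
        lo = np.searchsorted(starts, onset - 31 * 60.0)
        hi = np.searchsorted(starts, onset - 60.0)
        if hi > lo:
            usable += 1
    if usable < min_seizures:
        reasons.append(
            f"fewer than {min_seizures} usable seizures ({usable} of "
            f"{schedule.n_seizures} preceded by non-zero HFO rate)"
        )
    return {"included": not reasons, "usable_seizures": usable,
            "hours": hours, "reasons": reasons}


def validate_inputs(config: RunConfig) -> dict:
    """Static config validation (ranges, thresholds)."""
    problems = []
    if not 0.5 <= config.auc_threshold <= 1.0:
        problems.append("auc_threshold out of range")
    if not 0 < config.alpha < 1:
        problems.append("alpha out of range")
    if config.recording_duration_s <= config.n_seizures * config.min_seizure_gap_s:
        problems.append("recording too short for the requested seizure count")
    return {"ok": not problems, "problems": problems}


def schedule_model_fits(
    n_patients: int,
    window_lengths: tuple[int, ...] = WINDOW_LENGTHS,
    n_repeats: int = 10,
) -> list[tuple[int, int, int]]:
    """Enumerate every (patient, window length, repeat) model-fit task."""
    return [
        (p, L, r)
        for p in range(n_patients)
        for L in window_lengths
        for r in range(n_repeats)
    ]


def simulate_patient_observations(
    config: RunConfig,
    events: list[HFOEvent] | None = None,
    schedule: SeizureSchedule | None = None,
    channels: ChannelMap | None = None,
):
    """Simulate (or reuse) one patient's events and produce labeled
    observations per window length.  Returns (obs_by_window, extras)."""
    if channels is None:
        channels = make_channel_map(config.sim.n_soz, config.sim.n_out)
    if schedule is None:
        schedule = generate_seizure_schedule(
            config.n_seizures, config.recording_duration_s,
            config.min_seizure_gap_s, rng_seed=config.master_seed,
        )
    if events is None:
        sim = dataclasses.replace(config.sim, rng_seed=config.master_seed)
        events = simulate_event_stream(schedule, channels, sim)
    series = compute_chfo_rate(events, channels, schedule.recording_duration)
    obs_by_window = {}
    logs = {}
    for L in config.window_lengths:
        feats = build_feature_matrix(series, FeatureWindowConfig(L))
        obs, log1 = label_windows(feats, schedule, L)
        obs, log2 = apply_data_gap_exclusions(
            obs, file_bounds=(0.0, schedule.recording_duration)
        )
        obs_by_window[L] = obs
        logs[L] = (log1, log2)
    extras = {"schedule": schedule, "channels": channels, "events": events,
              "series": series, "exclusions": logs}
    return obs_by_window, extras


def run_all(config: RunConfig) -> Path:
    """Execute every stage into ``config.out_dir``; reruns with an unchanged
    config resume from cached stage outputs."""
    run = _Run(Path(config.out_dir))
    t0 = time.time()

    # ---- simulate -------------------------------------------------------
    sim_key = _config_hash("simulate", config.sim, config.n_seizures,
                           config.recording_duration_s,
                           config.min_seizure_gap_s, config.master_seed,
                           config.synthesize_signal)
    schedule_p = run.dir / "schedule.csv"
    channels_p = run.dir / "channels.csv"
    events_p = run.dir / "events_true.csv"
    signal_p = run.dir / "signal.bin"
    sim_outputs = [schedule_p, channels_p, events_p] + (
        [signal_p] if config.synthesize_signal else []
    )
    if run.cached("simulate", sim_key, sim_outputs):
        schedule = hio.read_schedule_csv(schedule_p)
        channels = hio.read_channel_map_csv(channels_p)
        events = hio.read_events_csv(events_p)
    else:
        channels = make_channel_map(config.sim.n_soz, config.sim.n_out)
        schedule = generate_seizure_schedule(
            config.n_seizures, config.recording_duration_s,
            config.min_seizure_gap_s, rng_seed=config.master_seed,
        )
        sim = dataclasses.replace(config.sim, rng_seed=config.master_seed)
        events = simulate_event_stream(schedule, channels, sim)
        hio.write_schedule_csv(schedule_p, schedule)
        hio.write_channel_map_csv(channels_p, channels)
        hio.write_events_csv(events_p, events, channels)
        if config.synthesize_signal:
            segment = synthesize_ieeg(events, channels, sim,
                                      schedule.recording_duration)
            hio.write_signal_bin(signal_p, segment)
        run.commit("simulate", sim_key)
    run.log("simulate", seed=config.master_seed, n_events=len(events),
            n_seizures=schedule.n_seizures)

    # ---- detect ---------------------------------------------------------
    det_key = _config_hash("detect", sim_key, config.detector,
                           config.synthesize_signal)
    detected_p = run.dir / "events_detected.csv"
    if run.cached("detect", det_key, [detected_p]):
        detected = hio.read_events_csv(detected_p)
    else:
        if config.synthesize_signal:
            segment = hio.read_signal_bin(signal_p)
            ref = common_average_reference(segment, channels)
            detected = pseudo_prospective_detect(ref, channels, config.detector)
            detected = redact_artifacts(detected, ref)
        else:
            # detect-from-events mode: simulated streams stand in for
            # detector output
            detected = events
        hio.write_events_csv(detected_p, detected, channels)
        run.commit("detect", det_key)
    run.log("detect", n_events=len(detected),
            mode="signal" if config.synthesize_signal else "events")

    # ---- rates + features + labels -------------------------------------
    feat_key = _config_hash("features", det_key, config.window_lengths)
    series = compute_chfo_rate(detected, channels, schedule.recording_duration)
    hio.write_rates_csv(run.dir / "rates.csv", series)
    obs_by_window = {}
    for L in config.window_lengths:
        feats = build_feature_matrix(series, FeatureWindowConfig(L))
        hio.write_features_csv(run.dir / f"features_{L:02d}.csv", feats)
        obs, log1 = label_windows(feats, schedule, L)
        obs, log2 = apply_data_gap_exclusions(
            obs, file_bounds=(0.0, schedule.recording_duration)
        )
        obs_by_window[L] = obs
        merged = log1
        merged.records.extend(log2.records)
        hio.write_exclusions_csv(run.dir / f"exclusions_{L:02d}.csv", merged)
        hio.write_observations_csv(run.dir / f"observations_{L:02d}.csv", obs)
        run.log("label", window_len_min=L,
                n_preictal=sum(o.label == "preictal" for o in obs),
                n_interictal=sum(o.label == "interictal" for o in obs),
                excluded=merged.counts())
    run.commit("features", feat_key)

    # ---- train + evaluate ----------------------------------------------
    results = run_patient(obs_by_window, config.n_repeats,
                          base_seed=config.master_seed)
    manifest = pd.DataFrame(
        {
            "window_len_min": [r.window_len_min for r in results],
            "repeat": [r.repeat for r in results],
            "converged": [r.model.converged for r in results],
            "test_auc": [r.test_auc for r in results],
            "lambda": [r.model.lam for r in results],
        }
    )
    manifest.to_csv(run.dir / "runs.csv", index=False, float_format="%.6f")
    for r in results:
        hio.write_model_json(
            run.dir / f"model_{r.window_len_min:02d}_{r.repeat:02d}.json",
            r.model,
        )
    summary = summarize_patient(results, config.n_perm,
                                seed=config.master_seed,
                                auc_threshold=config.auc_threshold,
                                alpha=config.alpha)
    summary.to_frame().to_csv(run.dir / "summary.csv", index=False,
                              float_format="%.6f")
    run.log("evaluate", n_models=len(results),
            responder=summary.responder, elapsed_s=round(time.time() - t0, 2))
    return run.dir
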