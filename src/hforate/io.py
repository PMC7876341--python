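"""Readers and writers for the pipeline's standard file formats.

Times are serialized as seconds from file start with 6 decimal places; all
tables are plain CSV.  Raw multichannel signal is stored as a float32
binary matrix with a JSON sidecar header, or read from EDF via mne.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ChannelMap, EEGSegment, HFOEvent, events_from_frame, events_to_frame
from .labeling import ExclusionLog, LabeledObservation, observations_to_frame
from .model import FittedModel
from .rates import FEATURE_NAMES, FeatureVector, RateSeries, features_to_frame
from .synthetic import SeizureSchedule

FLOAT_FMT = "%.6f"


def write_events_csv(path, events: list[HFOEvent],
                     channels: ChannelMap | None = None) -> None:
    df = events_to_frame(events)
    if channels is not None:
        groups = {c.channel_id: c.group for c in channels.channels}
        df.insert(1, "group", [groups.get(c, "") for c in df["channel_id"]])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_events_csv(path) -> list[HFOEvent]:
    return events_from_frame(pd.read_csv(path))


def write_schedule_csv(path, schedule: SeizureSchedule) -> None:
    with open(path, "w") as fh:
        fh.write(f"# recording_duration_s={schedule.recording_duration:.6f}\n")
        pd.DataFrame(
            {"onset_s": schedule.onsets, "offset_s": schedule.offsets}
        ).to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_schedule_csv(path) -> SeizureSchedule:
    with open(path) as fh:
        header = fh.readline().strip()
        duration = float(header.split("=", 1)[1])
        df = pd.read_csv(fh)
    return SeizureSchedule(df["onset_s"].to_numpy(),
                           df["offset_s"].to_numpy(), duration)


def write_channel_map_csv(path, channels: ChannelMap) -> None:
    channels.to_frame().to_csv(path, index=False)


def read_channel_map_csv(path) -> ChannelMap:
    return ChannelMap.from_frame(pd.read_csv(path))


def write_rates_csv(path, series: RateSeries) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_channels_soz={series.n_channels_soz},"
                 f"n_channels_out={series.n_channels_out}\n")
        series.to_frame().to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_rates_csv(path) -> RateSeries:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split(","))
        df = pd.read_csv(fh)
    return RateSeries(df["t_s"].to_numpy(), df["rate_soz"].to_numpy(),
                      df["rate_out"].to_numpy(),
                      int(meta["n_channels_soz"]), int(meta["n_channels_out"]))


def write_features_csv(path, features: list[FeatureVector]) -> None:
    df = features_to_frame(features)
    if features:
        df.insert(1, "window_len_min", [f.window_len_min for f in features])
    df.to_csv(path, index=False, float_format="%.8g")


def read_features_csv(path) -> list[FeatureVector]:
    df = pd.read_csv(path)
    return [
        FeatureVector(row[list(FEATURE_NAMES)].to_numpy(dtype=float),
                      float(row["window_end_s"]), int(row["window_len_min"]))
        for _, row in df.iterrows()
    ]


def write_observations_csv(path, observations: list[LabeledObservation]) -> None:
    observations_to_frame(observations).to_csv(
        path, index=False, float_format="%.8g"
    )


def read_observations_csv(path) -> list[LabeledObservation]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        L = int(round((row["window_end_s"] - row["window_start_s"]) / 60.0))
        fv = FeatureVector(row[list(FEATURE_NAMES)].to_numpy(dtype=float),
                           float(row["window_end_s"]), L)
        si = row["seizure_index"]
        out.append(LabeledObservation(
            fv, str(row["label"]), None if pd.isna(si) else int(si)))
    return out


def write_exclusions_csv(path, log: ExclusionLog) -> None:
    log.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def write_model_json(path, model: FittedModel) -> None:
    payload = {
        "intercept": model.intercept,
        "coef": model.named_coef(),
        "lambda": None if np.isnan(model.lam) else model.lam,
        "k_inner": model.k_inner,
        "converged": model.converged,
        "center": dict(zip(model.feature_names, model.center.tolist())),
        "scale": dict(zip(model.feature_names, model.scale.tolist())),
        "dropped": list(model.dropped),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_model_json(path) -> FittedModel:
    d = json.loads(Path(path).read_text())
    names = tuple(FEATURE_NAMES)
    return FittedModel(
        intercept=float(d["intercept"]),
        coef=np.array([d["coef"][n] for n in names]),
        lam=np.nan if d["lambda"] is None else float(d["lambda"]),
        k_inner=int(d["k_inner"]),
        converged=bool(d["converged"]),
        center=np.array([d["center"][n] for n in names]),
        scale=np.array([d["scale"][n] for n in names]),
        feature_names=names,
        dropped=tuple(d["dropped"]),
    )


def write_signal_bin(path, segment: EEGSegment) -> None:
    """Raw signal as a little-endian float32 (channels x samples) matrix
    plus a JSON header next to it."""
    path = Path(path)
    segment.samples.astype("<f4").tofile(path)
    header = {
        "format": "hforate-raw-v1",
        "dtype": "<f4",
        "order": "C",
        "units": "uV",
        "n_channels": segment.n_channels,
        "n_samples": segment.n_samples,
        "sampling_rate": segment.sampling_rate,
        "channel_ids": segment.channel_ids,
        "start_time": segment.start_time,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(header, indent=1)
    )


def read_signal_bin(path) -> EEGSegment:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=header["dtype"]).reshape(
        header["n_channels"], header["n_samples"]
    )
    return EEGSegment(data.astype(np.float64), header["sampling_rate"],
                      list(header["channel_ids"]), header["start_time"])


def read_edf(path, channel_ids: list[str] | None = None) -> EEGSegment:
    """Read an EDF recording into physical units (microvolts)."""
    import mne  # heavy import, kept local

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channel_ids is not None:
        raw.pick(channel_ids)
    data = raw.get_data() * 1e6  # mne returns volts
    return EEGSegment(data, float(raw.info["sfreq"]), list(raw.ch_names))
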