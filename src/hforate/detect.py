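"""Causal ("pseudo-prospective") RMS-based HFO detection.

The detector is the classic root-mean-square approach: the 80-500 Hz
band-passed signal is reduced to a short-window RMS trace; samples exceeding
the background mean by a multiple of the background standard deviation form
candidate events, which must last a minimum duration and contain a minimum
number of rectified-signal peaks.  To emulate real-time operation, detection
is emitted in 30-s increments and the background statistics for each
increment are computed from the *previous* 10 min only, so no event ever
depends on future data and no event starts before the first 10 min of a
file.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import filtfilt, find_peaks, firwin, kaiserord

from .core import ChannelMap, EEGSegment, HFOEvent, sort_events

__all__ = [
    "DetectorConfig",
    "BackgroundStats",
    "common_average_reference",
    "bandpass_filter",
    "compute_background",
    "detect_epoch",
    "pseudo_prospective_detect",
    "redact_artifacts",
]

log = logging.getLogger(__name__)


@dataclass
class DetectorConfig:
    """RMS-detector settings (canonical Staba-lineage defaults)."""

    band: tuple[float, float] = (80.0, 500.0)
    rms_window_ms: float = 3.0
    threshold_sd: float = 5.0
    min_duration_ms: float = 6.0
    min_peaks: int = 6
    peak_threshold_sd: float = 3.0
    background_len_s: float = 600.0
    emit_len_s: float = 30.0
    merge_gap_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.background_len_s <= self.emit_len_s:
            raise ValueError("background_len_s must exceed emit_len_s")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("invalid band")


@dataclass
class BackgroundStats:
    """Per-channel background statistics of the band-passed signal.

    ``rms`` holds (mean, sd) of the short-window RMS trace; ``rect`` holds
    (mean, sd) of the rectified signal, used for the peak criterion.
    """

    rms: dict[str, tuple[float, float]] = field(default_factory=dict)
    rect: dict[str, tuple[float, float]] = field(default_factory=dict)


def common_average_reference(
    segment: EEGSegment, channels: ChannelMap
) -> EEGSegment:
    """Subtract, per sample, the mean across all channels of each electrode
    type (depths together, grids together, ...).

    A type with a single channel is passed through unchanged with a warning:
    re-referencing it would zero the signal.
    """
    out = segment.samples.copy()
    for etype, ids in channels.by_type().items():
        rows = [segment.channel_ids.index(i) for i in ids if i in segment.channel_ids]
        if len(rows) < 2:
            if rows:
                log.warning(
                    "electrode type %s has a single channel; left unreferenced",
                    etype,
                )
            continue
        out[rows] -= out[rows].mean(axis=0, keepdims=True)
    return EEGSegment(out, segment.sampling_rate, list(segment.channel_ids),
                      segment.start_time)


def _design_fir(fs: float, band: tuple[float, float]) -> np.ndarray:
    nyq = fs / 2.0
    if band[1] >= nyq:
        raise ValueError(f"band edge {band[1]} Hz >= Nyquist {nyq} Hz")
    # transition narrow enough that 0.5x the low edge is in the stop band
    width = band[0] / 2.0
    numtaps, beta = kaiserord(ripple=45.0, width=width / nyq)
    numtaps |= 1  # odd length -> exactly linear phase, integer delay
    return firwin(numtaps, list(band), window=("kaiser", beta),
                  pass_zero=False, fs=fs)


def bandpass_filter(
    segment: EEGSegment, band: tuple[float, float] = (80.0, 500.0)
) -> EEGSegment:
    """Zero-phase FIR band-pass of every channel."""
    taps = _design_fir(segment.sampling_rate, band)
    if segment.n_samples <= 3 * taps.size:
        raise ValueError("segment too short for the band-pass filter")
    filtered = filtfilt(taps, [1.0], segment.samples, axis=1)
    return EEGSegment(filtered, segment.sampling_rate,
                      list(segment.channel_ids), segment.start_time)


def _moving_rms(x: np.ndarray, fs: float, window_ms: float) -> np.ndarray:
    w = max(1, int(round(window_ms * fs / 1000.0)))
    return np.sqrt(uniform_filter1d(x * x, size=w, mode="nearest"))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [i0, i1) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return list(zip(starts.tolist(), ends.tolist()))


def _detect_channel(
    xf: np.ndarray,
    rms: np.ndarray,
    fs: float,
    rms_bg: tuple[float, float],
    rect_bg: tuple[float, float],
    config: DetectorConfig,
) -> list[tuple[int, int, float]]:
    """Candidate events on one channel, as (i0, i1, peak_rms) sample runs."""
    rms_mean, rms_sd = rms_bg
    rect_mean, rect_sd = rect_bg
    if rms_sd == 0:
        warnings.warn("flat background (zero RMS variance); no detections")
        return []
    mask = rms > rms_mean + config.threshold_sd * rms_sd
    runs = _runs(mask)
    if not runs:
        return []
    # merge candidates closer than merge_gap_ms
    gap = int(round(config.merge_gap_ms * fs / 1000.0))
    merged = [list(runs[0])]
    for i0, i1 in runs[1:]:
        if i0 - merged[-1][1] < gap:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    min_len = config.min_duration_ms * fs / 1000.0
    peak_h = rect_mean + config.peak_threshold_sd * rect_sd
    out = []
    for i0, i1 in merged:
        if i1 - i0 < min_len:
            continue
        peaks, _ = find_peaks(np.abs(xf[i0:i1]), height=peak_h)
        if peaks.size < config.min_peaks:
            continue
        out.append((int(i0), int(i1), float(rms[i0:i1].max())))
    return out


def compute_background(
    filtered: EEGSegment, config: DetectorConfig | None = None
) -> BackgroundStats:
    """Background statistics of a band-passed segment (mean/SD of the RMS
    trace and of the rectified signal), per channel."""
    config = config or DetectorConfig()
    bg = BackgroundStats()
    for cid, x in zip(filtered.channel_ids, filtered.samples):
        rms = _moving_rms(x, filtered.sampling_rate, config.rms_window_ms)
        bg.rms[cid] = (float(rms.mean()), float(rms.std()))
        ax = np.abs(x)
        bg.rect[cid] = (float(ax.mean()), float(ax.std()))
    return bg


def detect_epoch(
    filtered: EEGSegment,
    background: BackgroundStats,
    config: DetectorConfig | None = None,
) -> list[HFOEvent]:
    """Detect events in a band-passed epoch against given background stats."""
    config = config or DetectorConfig()
    fs = filtered.sampling_rate
    events = []
    for cid, x in zip(filtered.channel_ids, filtered.samples):
        rms = _moving_rms(x, fs, config.rms_window_ms)
        for i0, i1, pk in _detect_channel(
            x, rms, fs, background.rms[cid], background.rect[cid], config
        ):
            events.append(
                HFOEvent(cid, filtered.start_time + i0 / fs,
                         filtered.start_time + i1 / fs, pk)
            )
    return sort_events(events)


def pseudo_prospective_detect(
    recording: EEGSegment,
    channels: ChannelMap | None = None,
    config: DetectorConfig | None = None,
) -> list[HFOEvent]:
    """Detect HFOs causally over a whole recording.

    For every emission window [t, t+30 s) with t = 600, 630, ... the
    background statistics are taken from [t-600 s, t) only, and only events
    *starting* inside the emission window are reported; an event crossing the
    window end is kept whole and attributed to the window containing its
    start.  No event starts before the first 10 min.
    """
    config = config or DetectorConfig()
    fs = recording.sampling_rate
    bg_len, emit = config.background_len_s, config.emit_len_s
    if recording.duration <= bg_len:
        warnings.warn("recording no longer than the background window; "
                      "no events can be emitted")
        return []
    if channels is not None:
        keep = [i for i, c in enumerate(recording.channel_ids)
                if c in set(channels.ids())]
        recording = EEGSegment(recording.samples[keep], fs,
                               [recording.channel_ids[i] for i in keep],
                               recording.start_time)
    filtered = bandpass_filter(recording, config.band)
    ctx = int(round(1.0 * fs))  # 1-s context so boundary events stay whole
    events: list[HFOEvent] = []
    for cid, x in zip(filtered.channel_ids, filtered.samples):
        rms = _moving_rms(x, fs, config.rms_window_ms)
        ax = np.abs(x)
        t = bg_len
        while t + emit <= recording.duration + 1e-9:
            j0 = int(round(t * fs))
            j1 = int(round((t + emit) * fs))
            b0 = int(round((t - bg_len) * fs))
            rms_bg = (float(rms[b0:j0].mean()), float(rms[b0:j0].std()))
            rect_bg = (float(ax[b0:j0].mean()), float(ax[b0:j0].std()))
            s0 = max(0, j0 - ctx)
            s1 = min(x.size, j1 + ctx)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cands = _detect_channel(x[s0:s1], rms[s0:s1], fs, rms_bg,
                                        rect_bg, config)
            for i0, i1, pk in cands:
                if j0 <= s0 + i0 < j1:
                    events.append(
                        HFOEvent(cid,
                                 recording.start_time + (s0 + i0) / fs,
                                 recording.start_time + (s0 + i1) / fs, pk)
                    )
            t += emit
    return sort_events(events)


def find_artifact_intervals(
    segment: EEGSegment,
    slope_sd: float = 8.0,
    pad_s: float = 0.025,
    flat_min_s: float = 0.02,
) -> dict[str, list[tuple[float, float]]]:
    """Locate sharp transients and amplitude-saturation stretches.

    Sharp transients are sample-to-sample steps exceeding ``slope_sd`` robust
    standard deviations (1.4826 x MAD) of the channel's first difference;
    saturation is a run of identical values at least ``flat_min_s`` long.
    """
    fs = segment.sampling_rate
    out: dict[str, list[tuple[float, float]]] = {}
    for cid, x in zip(segment.channel_ids, segment.samples):
        d = np.diff(x)
        sd = 1.4826 * np.median(np.abs(d - np.median(d)))
        intervals = []
        if sd > 0:
            for i in np.flatnonzero(np.abs(d) > slope_sd * sd):
                intervals.append((segment.start_time + i / fs - pad_s,
                                  segment.start_time + (i + 1) / fs + pad_s))
        for i0, i1 in _runs(np.abs(d) < 1e-12):
            if (i1 - i0) / fs >= flat_min_s:
                intervals.append((segment.start_time + i0 / fs - pad_s,
                                  segment.start_time + (i1 + 1) / fs + pad_s))
        out[cid] = intervals
    return out


def redact_artifacts(
    events: list[HFOEvent], segment: EEGSegment, **kwargs
) -> list[HFOEvent]:
    """Drop events overlapping sharp-transient or saturation artifacts.

    A basic specificity stage (the clinical pipelines this emulates use a
    richer artifact battery); a pure filter, so output is a subset of input.
    """
    art = find_artifact_intervals(segment, **kwargs)
    kept = []
    for ev in events:
        bad = any(ev.start_s < b and a < ev.end_s
                  for a, b in art.get(ev.channel_id, ()))
        if not bad:
            kept.append(ev)
    return kept
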