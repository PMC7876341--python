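"""Synthetic seizure schedules, HFO event streams, and raw iEEG.

The generator emulates the structure of clinical intracranial monitoring:
per-channel HFO occurrences are drawn from inhomogeneous Poisson processes
whose baseline rates sit on the scale observed clinically (roughly 0.1-4
events/min/channel), with a configurable multiplicative modulation of
seizure-onset-zone intensity inside a preictal horizon before each seizure.
Optionally, a raw multichannel signal is synthesized by embedding windowed
oscillatory bursts (80-500 Hz band) in 1/f background noise, so the detector
can be exercised against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Channel, ChannelMap, EEGSegment, HFOEvent, sort_events

__all__ = [
    "SeizureSchedule",
    "PreictalEffect",
    "SimConfig",
    "generate_seizure_schedule",
    "make_channel_map",
    "simulate_event_stream",
    "synthesize_ieeg",
]


@dataclass
class SeizureSchedule:
    """Clinician-style seizure onset/offset annotations for one recording."""

    onsets: np.ndarray
    offsets: np.ndarray
    recording_duration: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.float64)
        self.offsets = np.asarray(self.offsets, dtype=np.float64)
        if self.onsets.shape != self.offsets.shape:
            raise ValueError("onsets and offsets must have equal length")
        if self.onsets.size:
            if np.any(np.diff(self.onsets) <= 0):
                raise ValueError("onsets must be strictly increasing")
            if np.any(self.offsets <= self.onsets):
                raise ValueError("every offset must follow its onset")
            if np.any(self.offsets[:-1] >= self.onsets[1:]):
                raise ValueError("every offset must precede the next onset")
            if self.onsets[0] < 0 or self.offsets[-1] > self.recording_duration:
                raise ValueError("seizure times outside [0, recording_duration]")

    @property
    def n_seizures(self) -> int:
        return int(self.onsets.size)


@dataclass
class PreictalEffect:
    """Multiplicative intensity modulation inside the preictal horizon.

    ``linear_ramp`` scales intensity from 1x at (onset - horizon) linearly up
    to ``magnitude``x at onset; ``step`` applies ``magnitude``x throughout the
    horizon; ``none`` leaves the baseline untouched.
    """

    shape: str = "none"  # none | linear_ramp | step
    horizon_min: float = 30.0
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("none", "linear_ramp", "step"):
            raise ValueError(f"unknown preictal effect shape {self.shape!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.horizon_min <= 0:
            raise ValueError("horizon must be positive")


@dataclass
class SimConfig:
    """Study conditions for one synthetic patient.

    Baseline rates default to the clinical cohort scale (mean ~1.6 SOZ /
    ~0.5 OUT events/min/channel); channel counts default to a typical
    implant (8 SOZ channels, 40 OUT channels).
    """

    baseline_rate_soz: float = 1.5  # events/min/channel
    baseline_rate_out: float = 0.5
    preictal_effect: PreictalEffect = field(default_factory=PreictalEffect)
    out_effect: PreictalEffect | None = None  # optional OUT-channel modulation
    #: slow brain-state (sleep/wake) modulation of all baselines: intensity
    #: is multiplied by 1 + amplitude*sin(2*pi*t/period + phase), with a
    #: random patient-level phase.  HFO rates are strongly state-dependent
    #: in clinical recordings; 0 disables it.
    circadian_amplitude: float = 0.5
    circadian_period_h: float = 24.0
    n_soz: int = 8
    n_out: int = 40
    sampling_rate: float = 4096.0
    ictal_rate_factor: float = 1.0  # intensity multiplier during seizures
    event_duration_ms: float = 50.0
    burst_freq_hz: float = 140.0
    burst_snr: float = 10.0
    background_rms_uv: float = 20.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate_soz < 0 or self.baseline_rate_out < 0:
            raise ValueError("baseline rates must be >= 0")
        if self.ictal_rate_factor < 0:
            raise ValueError("ictal rate factor must be >= 0")
        if not 0 <= self.circadian_amplitude < 1:
            raise ValueError("circadian amplitude must be in [0, 1)")
        if self.sampling_rate < 2000:
            raise ValueError("sampling rate must be >= 2000 Hz")


def generate_seizure_schedule(
    n_seizures: int,
    duration: float,
    min_gap: float = 7200.0,
    rng_seed: int = 0,
    seizure_duration_s: tuple[float, float] = (60.0, 120.0),
) -> SeizureSchedule:
    """Draw a random seizure schedule with all inter-onset gaps >= min_gap.

    Onsets are a uniform random packing: n sorted uniforms over the slack
    ``duration - n*min_gap`` are spread out by ``min_gap`` each, which makes
    every configuration with the gap constraint equally likely.
    """
    if n_seizures < 0:
        raise ValueError("n_seizures must be >= 0")
    if n_seizures == 0:
        return SeizureSchedule(np.empty(0), np.empty(0), duration)
    max_dur = seizure_duration_s[1]
    if min_gap <= max_dur:
        raise ValueError("min_gap must exceed the maximum seizure duration")
    slack = duration - n_seizures * min_gap
    if slack <= 0:
        raise ValueError(
            f"cannot place {n_seizures} seizures with min_gap={min_gap} s in "
            f"{duration} s of recording"
        )
    rng = np.random.default_rng(rng_seed)
    u = np.sort(rng.uniform(0.0, slack, n_seizures))
    onsets = u + min_gap * np.arange(1, n_seizures + 1)
    durs = rng.uniform(seizure_duration_s[0], seizure_duration_s[1], n_seizures)
    offsets = np.minimum(onsets + durs, duration)
    return SeizureSchedule(onsets, offsets, duration)


def make_channel_map(
    n_soz: int = 8, n_out: int = 40, n_rv: int = 0, electrode_type: str = "depth"
) -> ChannelMap:
    """Convenience builder for a synthetic implant channel map."""
    chans = (
        [Channel(f"SOZ{i:02d}", "SOZ", electrode_type) for i in range(n_soz)]
        + [Channel(f"OUT{i:02d}", "OUT", electrode_type) for i in range(n_out)]
        + [Channel(f"RV{i:02d}", "RV", electrode_type) for i in range(n_rv)]
    )
    return ChannelMap(chans)


def _modulation(t: np.ndarray, schedule: SeizureSchedule, effect: PreictalEffect,
                ictal_factor: float) -> np.ndarray:
    """Multiplicative intensity factor at times ``t`` (vectorized)."""
    f = np.ones_like(t)
    horizon = effect.horizon_min * 60.0
    for onset, offset in zip(schedule.onsets, schedule.offsets):
        if effect.shape != "none":
            in_pre = (t >= onset - horizon) & (t < onset)
            if effect.shape == "linear_ramp":
                frac = 1.0 - (onset - t[in_pre]) / horizon
                f[in_pre] = 1.0 + (effect.magnitude - 1.0) * frac
            else:  # step
                f[in_pre] = effect.magnitude
        in_ictal = (t >= onset) & (t < offset)
        f[in_ictal] = ictal_factor
    return f


def _thin_channel(
    rng: np.random.Generator,
    baseline: float,
    duration: float,
    schedule: SeizureSchedule,
    effect: PreictalEffect,
    ictal_factor: float,
    circ: tuple[float, float, float],
) -> np.ndarray:
    """Inhomogeneous Poisson event start times via thinning."""
    amp, period_s, phase = circ
    lam_max = (baseline * (1.0 + amp)
               * max(1.0, effect.magnitude, ictal_factor) / 60.0)  # per s
    if lam_max == 0:
        return np.empty(0)
    n = rng.poisson(lam_max * duration)
    t = np.sort(rng.uniform(0.0, duration, n))
    lam_t = (baseline / 60.0) * _modulation(t, schedule, effect, ictal_factor)
    if amp > 0:
        lam_t = lam_t * (1.0 + amp * np.sin(2 * np.pi * t / period_s + phase))
    if np.any(lam_t < 0):
        raise ValueError("negative intensity encountered")
    keep = rng.uniform(0.0, lam_max, t.size) < lam_t
    return t[keep]


def simulate_event_stream(
    schedule: SeizureSchedule, channels: ChannelMap, config: SimConfig
) -> list[HFOEvent]:
    """Simulate per-channel HFO event streams.

    Each channel is an independent inhomogeneous Poisson process sampled by
    thinning; SOZ channels carry ``config.preictal_effect`` inside each
    preictal horizon and OUT channels carry ``config.out_effect`` if given.
    Deterministic for a fixed ``config.rng_seed``.
    """
    root = np.random.SeedSequence(config.rng_seed)
    # one sub-stream per channel plus one for patient-level parameters
    *seeds, patient_ss = root.spawn(len(channels.channels) + 1)
    phase = float(np.random.default_rng(patient_ss).uniform(0, 2 * np.pi))
    circ = (config.circadian_amplitude,
            config.circadian_period_h * 3600.0, phase)
    dur_ev = config.event_duration_ms / 1000.0
    none = PreictalEffect("none")
    events: list[HFOEvent] = []
    for ch, ss in zip(channels.channels, seeds):
        if ch.group == "SOZ":
            baseline, effect = config.baseline_rate_soz, config.preictal_effect
        elif ch.group == "OUT":
            baseline = config.baseline_rate_out
            effect = config.out_effect if config.out_effect is not None else none
        else:  # RV channels: baseline OUT-like stream (excluded downstream)
            baseline, effect = config.baseline_rate_out, none
        rng = np.random.default_rng(ss)
        starts = _thin_channel(
            rng, baseline, schedule.recording_duration, schedule, effect,
            config.ictal_rate_factor, circ,
        )
        starts = starts[starts + dur_ev <= schedule.recording_duration]
        events.extend(
            HFOEvent(ch.channel_id, float(s), float(s + dur_ev)) for s in starts
        )
    return sort_events(events)


def _pink_noise(rng: np.random.Generator, n: int, fs: float, rms: float) -> np.ndarray:
    """Gaussian 1/f (pink) noise with the requested broadband RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n)
    return x * (rms / np.sqrt(np.mean(x**2)))


def _band_rms(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """RMS of the part of ``x`` inside ``band`` (spectral, Parseval)."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.sqrt(spec[sel].sum() / (x.size * x.size / 2.0)))


def synthesize_ieeg(
    events: list[HFOEvent],
    channels: ChannelMap,
    config: SimConfig,
    duration: float,
    band: tuple[float, float] = (80.0, 500.0),
) -> EEGSegment:
    """Embed Hann-windowed sinusoidal bursts in per-channel 1/f noise.

    Burst amplitude is ``config.burst_snr`` times the channel's background
    RMS inside ``band``; channel order matches the channel map.
    """
    fs = config.sampling_rate
    if fs < 2000:
        raise ValueError("sampling rate must be >= 2000 Hz")
    n = int(round(duration * fs))
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 0x51]))
    data = np.empty((len(channels), n))
    idx = {c.channel_id: i for i, c in enumerate(channels.channels)}
    for i in range(len(channels)):
        data[i] = _pink_noise(rng, n, fs, config.background_rms_uv)
    band_rms = {
        c.channel_id: _band_rms(data[idx[c.channel_id]], fs, band)
        for c in channels.channels
    }
    for ev in events:
        if ev.start_s < 0 or ev.end_s > duration:
            raise ValueError(f"event outside recording: {ev}")
        i = idx[ev.channel_id]
        i0 = int(round(ev.start_s * fs))
        i1 = int(round(ev.end_s * fs))
        m = i1 - i0
        if m < 2:
            continue
        tt = np.arange(m) / fs
        burst = np.hanning(m) * np.sin(2 * np.pi * config.burst_freq_hz * tt)
        data[i, i0:i1] += config.burst_snr * band_rms[ev.channel_id] * burst
    return EEGSegment(data, fs, [c.channel_id for c in channels.channels])
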