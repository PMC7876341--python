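"""Shared domain objects: channels, detected events, raw-signal segments.

Times are always seconds from the start of the recording file; intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Channel groups. SOZ = clinician-defined seizure-onset zone, OUT = outside
#: both the SOZ and the resected volume, RV = inside the resected volume
#: (RV-only channels are excluded from rate analysis).
GROUPS = ("SOZ", "OUT", "RV")
ELECTRODE_TYPES = ("grid", "strip", "depth")


@dataclass(frozen=True)
class Channel:
    channel_id: str
    group: str
    electrode_type: str = "depth"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown channel group {self.group!r}")
        if self.electrode_type not in ELECTRODE_TYPES:
            raise ValueError(f"unknown electrode type {self.electrode_type!r}")


@dataclass
class ChannelMap:
    """Assignment of every channel to a SOZ / OUT / RV group."""

    channels: list[Channel]

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate channel ids in channel map")

    def __iter__(self) -> Iterable[Channel]:
        return iter(self.channels)

    def __len__(self) -> int:
        return len(self.channels)

    def ids(self, group: str | None = None) -> list[str]:
        if group is None:
            return [c.channel_id for c in self.channels]
        return [c.channel_id for c in self.channels if c.group == group]

    def n(self, group: str) -> int:
        return len(self.ids(group))

    def group_of(self, channel_id: str) -> str:
        for c in self.channels:
            if c.channel_id == channel_id:
                return c.group
        raise KeyError(channel_id)

    def by_type(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for c in self.channels:
            out.setdefault(c.electrode_type, []).append(c.channel_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_id": [c.channel_id for c in self.channels],
                "group": [c.group for c in self.channels],
                "electrode_type": [c.electrode_type for c in self.channels],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChannelMap":
        return cls(
            [
                Channel(str(r.channel_id), str(r.group), str(r.electrode_type))
                for r in df.itertuples()
            ]
        )


@dataclass(frozen=True)
class HFOEvent:
    """One detected (or simulated) high-frequency oscillation."""

    channel_id: str
    start_s: float
    end_s: float
    peak_rms: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_s < self.end_s):
            raise ValueError(
                f"invalid event interval [{self.start_s}, {self.end_s})"
            )


def events_to_frame(events: Sequence[HFOEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "channel_id": [e.channel_id for e in events],
            "start_s": [e.start_s for e in events],
            "end_s": [e.end_s for e in events],
            "peak_rms": [e.peak_rms for e in events],
        }
    )


def events_from_frame(df: pd.DataFrame) -> list[HFOEvent]:
    peak = df["peak_rms"] if "peak_rms" in df.columns else [None] * len(df)
    return [
        HFOEvent(str(c), float(s), float(e), None if pd.isna(p) else float(p))
        for c, s, e, p in zip(df["channel_id"], df["start_s"], df["end_s"], peak)
    ]


def sort_events(events: Iterable[HFOEvent]) -> list[HFOEvent]:
    return sorted(events, key=lambda e: (e.start_s, e.channel_id))


@dataclass
class EEGSegment:
    """A block of multichannel iEEG in physical units (microvolts).

    ``samples`` has shape (n_channels, n_samples); row order matches
    ``channel_ids``.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_ids: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x samples)")
        if self.samples.shape[0] != len(self.channel_ids):
            raise ValueError("channel_ids length must match samples rows")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, channel_id: str) -> np.ndarray:
        return self.samples[self.channel_ids.index(channel_id)]
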