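"""Continuous HFO rate (cHFO) and rate features.

The cHFO rate is the number of HFOs per minute per channel in a 1-min window
slid forward in 1-s steps, computed separately for the SOZ and OUT channel
groups (RV-only channels are excluded).  Eight descriptive statistics of the
rate trace inside a 30-, 15-, or 10-min "feature window" per group give a
16-dimensional feature vector: mean, variance, ordinary-least-squares slope,
the three quartiles, skewness, and excess kurtosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ChannelMap, HFOEvent

__all__ = [
    "STAT_NAMES",
    "FEATURE_NAMES",
    "RateSeries",
    "FeatureWindowConfig",
    "FeatureVector",
    "compute_chfo_rate",
    "extract_features",
    "build_feature_matrix",
]

STAT_NAMES = ("MEAN", "VAR", "SLOPE", "Q1", "Q2", "Q3", "SKEW", "KURT")
#: Canonical feature order: all SOZ statistics then all OUT statistics.
FEATURE_NAMES = tuple(f"{s}-{g}" for g in ("SOZ", "OUT") for s in STAT_NAMES)


@dataclass
class RateSeries:
    """Group-wise cHFO rate on a 1-s grid.

    ``rate_*[i]`` is the events/min/channel rate over the minute ending at
    ``times[i]``, i.e. the window ``[times[i] - 60, times[i])``.
    """

    times: np.ndarray
    rate_soz: np.ndarray
    rate_out: np.ndarray
    n_channels_soz: int
    n_channels_out: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.rate_soz = np.asarray(self.rate_soz, dtype=np.float64)
        self.rate_out = np.asarray(self.rate_out, dtype=np.float64)
        if not (self.times.shape == self.rate_soz.shape == self.rate_out.shape):
            raise ValueError("times and rates must have equal shape")
        if self.times.size > 1 and not np.allclose(np.diff(self.times), 1.0):
            raise ValueError("rate grid spacing must be exactly 1 s")
        if np.any(self.rate_soz < 0) or np.any(self.rate_out < 0):
            raise ValueError("rates must be >= 0")

    def rate(self, group: str) -> np.ndarray:
        if group == "SOZ":
            return self.rate_soz
        if group == "OUT":
            return self.rate_out
        raise ValueError(f"unknown group {group!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.times, "rate_soz": self.rate_soz,
             "rate_out": self.rate_out}
        )


@dataclass
class FeatureWindowConfig:
    window_len_min: int = 30
    step_min: int = 1

    def __post_init__(self) -> None:
        if self.window_len_min not in (30, 15, 10):
            raise ValueError("window_len_min must be one of {30, 15, 10}")
        if self.step_min != 1:
            raise ValueError("feature windows advance on a 1-min grid")


@dataclass(eq=False)
class FeatureVector:
    """One 16-dimensional rate-feature observation.

    ``values`` follows :data:`FEATURE_NAMES`; the window is
    ``[window_end_s - 60*window_len_min, window_end_s)``.
    """

    values: np.ndarray
    window_end_s: float
    window_len_min: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (16,):
            raise ValueError("feature vector must have exactly 16 components")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def window_start_s(self) -> float:
        return self.window_end_s - 60.0 * self.window_len_min

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values.tolist()))


def compute_chfo_rate(
    events: list[HFOEvent], channels: ChannelMap, duration: float
) -> RateSeries:
    """Sliding 1-min / 1-s-step group rate from an event list.

    The rate at grid time t counts events *starting* in [t-60, t), summed
    over the group's channels and divided by the number of channels in the
    group.  Events on RV channels are ignored.
    """
    for g in ("SOZ", "OUT"):
        if channels.n(g) == 0:
            raise ValueError(f"channel group {g} is empty")
    groups = {c.channel_id: c.group for c in channels.channels}
    starts = {"SOZ": [], "OUT": []}
    for ev in events:
        g = groups.get(ev.channel_id)
        if g is None:
            raise KeyError(f"event on unknown channel {ev.channel_id!r}")
        if g in starts:
            starts[g].append(ev.start_s)
    t = np.arange(60.0, np.floor(duration) + 1.0)
    rates = {}
    for g in ("SOZ", "OUT"):
        s = np.sort(np.asarray(starts[g]))
        counts = np.searchsorted(s, t, "left") - np.searchsorted(s, t - 60.0, "left")
        rates[g] = counts / channels.n(g)
    return RateSeries(t, rates["SOZ"], rates["OUT"],
                      channels.n("SOZ"), channels.n("OUT"))


def _window_stats(w: np.ndarray) -> np.ndarray:
    """The 8 statistics for each row of a (n_windows, n_samples) matrix.

    Variance is the population (ddof=0) moment; skewness and kurtosis are
    moment-based (no bias correction), kurtosis is excess (Gaussian -> 0);
    both are defined as 0 on zero-variance rows.  The slope is the OLS slope
    of rate against time measured in minutes.
    """
    n = w.shape[1]
    mean = w.mean(axis=1)
    var = w.var(axis=1)
    tmin = np.arange(n) / 60.0  # minutes
    tc = tmin - tmin.mean()
    slope = (w - mean[:, None]) @ tc / np.dot(tc, tc)
    q1, q2, q3 = np.percentile(w, [25, 50, 75], axis=1, method="linear")
    nz = var > 0
    skew = np.zeros(w.shape[0])
    kurt = np.zeros(w.shape[0])
    if nz.any():
        skew[nz] = sps.skew(w[nz], axis=1, bias=True)
        kurt[nz] = sps.kurtosis(w[nz], axis=1, fisher=True, bias=True)
    return np.column_stack([mean, var, slope, q1, q2, q3, skew, kurt])


def extract_features(
    series: RateSeries, window: tuple[float, float], group: str
) -> dict[str, float]:
    """The 8 statistics of the rate samples inside ``[a, b)`` for one group."""
    a, b = window
    if b - a not in (600.0, 900.0, 1800.0):
        raise ValueError("window length must be 600, 900 or 1800 s")
    sel = (series.times >= a) & (series.times < b)
    x = series.rate(group)[sel]
    if x.size != int(b - a):
        raise ValueError(
            f"window [{a}, {b}) not fully covered by the rate series"
        )
    row = _window_stats(x[None, :])[0]
    return dict(zip(STAT_NAMES, row.tolist()))


def window_grid(series: RateSeries, window_len_min: int) -> np.ndarray:
    """End times (60-s multiples) of all feature windows the series covers."""
    L = 60.0 * window_len_min
    t0, t_last = series.times[0], series.times[-1]
    first_end = np.ceil(t0 / 60.0) * 60.0 + L
    ends = np.arange(first_end, t_last + 1.0 + 1e-9, 60.0)
    return ends[(ends - L >= t0) & (ends - 1 <= t_last)]


def build_feature_matrix(
    series: RateSeries, config: FeatureWindowConfig
) -> list[FeatureVector]:
    """One 16-dimensional FeatureVector per 1-min grid position."""
    L = int(60 * config.window_len_min)
    ends = window_grid(series, config.window_len_min)
    if ends.size == 0:
        return []
    t0 = series.times[0]
    idx_end = np.asarray(np.round(ends - t0), dtype=np.intp)
    offsets = np.arange(-L, 0)
    windows = {g: series.rate(g)[idx_end[:, None] + offsets[None, :]]
               for g in ("SOZ", "OUT")}
    stats = np.hstack([_window_stats(windows["SOZ"]),
                       _window_stats(windows["OUT"])])
    return [
        FeatureVector(row, float(e), config.window_len_min)
        for row, e in zip(stats, ends)
    ]


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    df = pd.DataFrame([f.values for f in features], columns=list(FEATURE_NAMES))
    df.insert(0, "window_end_s", [f.window_end_s for f in features])
    return df
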