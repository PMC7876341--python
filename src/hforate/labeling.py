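"""Preictal/interictal labeling of feature windows, with exclusion rules.

The preictal period is the 31 min before clinician-marked seizure onset (30
physiological minutes plus a 1-min buffer for onset-time uncertainty).  For
each seizure and window length, exactly one preictal observation is kept:
the latest feature window ending at least 1 min before onset.  Interictal
observations are consecutive, non-overlapping windows taken from the spans
that start 11 min after a seizure offset and end 31 min before the next
onset.  Everything else in the preictal zone, anything peri-ictal, anything
overlapping data gaps or the detector's 10-min warm-up, is discarded, and
every discarded window is logged with one primary reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rates import FeatureVector
from .synthetic import SeizureSchedule

__all__ = [
    "PREICTAL_ZONE_S",
    "BUFFER_S",
    "POSTICTAL_S",
    "LabeledObservation",
    "ExclusionRecord",
    "ExclusionLog",
    "label_windows",
    "apply_data_gap_exclusions",
]

PREICTAL_ZONE_S = 31 * 60.0  # zone before onset: buffer + 30 physiological min
BUFFER_S = 60.0              # last minute before onset, never used
POSTICTAL_S = 11 * 60.0      # exclusion after seizure offset

REASONS = (
    "periictal_other_seizure",
    "preictal_zone_nonpreictal",
    "missing_data",
    "detector_warmup",
    "postictal",
    "buffer",
    "off_tiling",
)


@dataclass(eq=False)
class LabeledObservation:
    feature: FeatureVector
    label: str  # "preictal" | "interictal"
    seizure_index: int | None = None

    def __post_init__(self) -> None:
        if self.label not in ("preictal", "interictal"):
            raise ValueError(f"unknown label {self.label!r}")
        if (self.label == "preictal") != (self.seizure_index is not None):
            raise ValueError("seizure_index is set iff the label is preictal")

    @property
    def window_len_min(self) -> int:
        return self.feature.window_len_min


@dataclass(frozen=True)
class ExclusionRecord:
    window_end_s: float
    window_len_min: int
    reason: str
    seizure_index: int | None = None


@dataclass
class ExclusionLog:
    records: list[ExclusionRecord] = field(default_factory=list)

    def add(self, end: float, L: int, reason: str,
            seizure_index: int | None = None) -> None:
        if reason not in REASONS:
            raise ValueError(f"unknown exclusion reason {reason!r}")
        self.records.append(ExclusionRecord(end, L, reason, seizure_index))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.reason] = out.get(r.reason, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_end_s": [r.window_end_s for r in self.records],
                "window_len_min": [r.window_len_min for r in self.records],
                "reason": [r.reason for r in self.records],
                "seizure_index": [r.seizure_index for r in self.records],
            }
        )


def _intersects(a0: float, a1: float, b0: float, b1: float) -> bool:
    """Do half-open intervals [a0, a1) and [b0, b1) intersect?"""
    return a0 < b1 and b0 < a1


def envelope(onset: float, offset: float) -> tuple[float, float]:
    """Peri-ictal envelope of one seizure: preictal zone + ictal + postictal."""
    return onset - PREICTAL_ZONE_S, offset + POSTICTAL_S


def interictal_spans(schedule: SeizureSchedule) -> list[tuple[float, float]]:
    """Admissible interictal spans: the complement of all envelopes."""
    spans = []
    prev_end = 0.0
    for onset, offset in zip(schedule.onsets, schedule.offsets):
        e0, e1 = envelope(onset, offset)
        if e0 > prev_end:
            spans.append((prev_end, e0))
        prev_end = max(prev_end, e1)
    if schedule.recording_duration > prev_end:
        spans.append((prev_end, schedule.recording_duration))
    return spans


def interictal_tiling(schedule: SeizureSchedule, window_len_min: int) -> set[float]:
    """Window end times of the non-overlapping interictal epoch tiling.

    Each admissible span is tiled with back-to-back windows anchored at the
    span start (rounded up to the 1-min grid); partial trailing windows are
    dropped.
    """
    L = 60.0 * window_len_min
    ends: set[float] = set()
    for s, t in interictal_spans(schedule):
        a = np.ceil(s / 60.0) * 60.0
        while a + L <= t + 1e-9:
            ends.add(a + L)
            a += L
    return ends


def preictal_candidates(
    schedule: SeizureSchedule, window_len_min: int
) -> list[float]:
    """Per seizure, the end time of the latest grid window ending at least
    1 min (the onset buffer) before onset."""
    return [float(np.floor((onset - BUFFER_S) / 60.0) * 60.0)
            for onset in schedule.onsets]


def label_windows(
    features: list[FeatureVector],
    schedule: SeizureSchedule,
    window_len_min: int | None = None,
) -> tuple[list[LabeledObservation], ExclusionLog]:
    """Assign preictal/interictal labels and apply the zone exclusion rules.

    Data-gap and warm-up exclusions are a separate pass
    (:func:`apply_data_gap_exclusions`).
    """
    if not features:
        return [], ExclusionLog()
    if window_len_min is None:
        window_len_min = features[0].window_len_min
    L = 60.0 * window_len_min
    excl = ExclusionLog()
    for f in features:
        if f.window_len_min != window_len_min:
            raise ValueError("mixed window lengths in one labeling pass")
        if abs(f.window_end_s % 60.0) > 1e-9:
            raise ValueError("feature windows must lie on the 1-min grid")

    by_end = {f.window_end_s: f for f in features}
    onsets, offsets = schedule.onsets, schedule.offsets

    # preictal selection, with redaction against *other* seizures' envelopes
    preictal_end: dict[float, int] = {}
    for k, cand in enumerate(preictal_candidates(schedule, window_len_min)):
        if cand not in by_end:
            excl.add(cand, window_len_min, "missing_data", k)
            continue
        w0, w1 = cand - L, cand
        redacted = False
        for j in range(len(onsets)):
            if j == k:
                continue
            e0, e1 = envelope(onsets[j], offsets[j])
            if _intersects(w0, w1, e0, e1):
                redacted = True
                break
        if redacted:
            excl.add(cand, window_len_min, "periictal_other_seizure", k)
        else:
            preictal_end[cand] = k

    tiling = interictal_tiling(schedule, window_len_min)

    observations: list[LabeledObservation] = []
    for f in features:
        e = f.window_end_s
        w0, w1 = e - L, e
        if e in preictal_end:
            observations.append(
                LabeledObservation(f, "preictal", preictal_end[e])
            )
            continue
        reason = None
        for k in range(len(onsets)):
            if _intersects(w0, w1, onsets[k], offsets[k] + POSTICTAL_S):
                reason = "postictal"
                break
        if reason is None:
            for k in range(len(onsets)):
                if _intersects(w0, w1, onsets[k] - BUFFER_S, onsets[k]):
                    reason = "buffer"
                    break
        if reason is None:
            for k in range(len(onsets)):
                if _intersects(w0, w1, onsets[k] - PREICTAL_ZONE_S,
                               onsets[k] - BUFFER_S):
                    reason = "preictal_zone_nonpreictal"
                    break
        if reason is not None:
            excl.add(e, window_len_min, reason)
        elif e in tiling:
            observations.append(LabeledObservation(f, "interictal"))
        else:
            # inside an admissible span but overlapping the epoch tiling
            excl.add(e, window_len_min, "off_tiling")
    return observations, excl


def apply_data_gap_exclusions(
    observations: list[LabeledObservation],
    gaps: list[tuple[float, float]] = (),
    file_bounds: tuple[float, float] | None = None,
    warmup_s: float = 600.0,
) -> tuple[list[LabeledObservation], ExclusionLog]:
    """Drop observations overlapping missing data or the detector warm-up.

    The first ``warmup_s`` seconds of the file are excluded because the
    causal detector emits no events there; any window intersecting a gap
    interval is excluded as missing data.  Output is a subset of the input.
    """
    file_start = file_bounds[0] if file_bounds is not None else 0.0
    excl = ExclusionLog()
    kept = []
    for obs in observations:
        w0, w1 = obs.feature.window_start_s, obs.feature.window_end_s
        if _intersects(w0, w1, file_start, file_start + warmup_s):
            excl.add(w1, obs.window_len_min, "detector_warmup",
                     obs.seizure_index)
        elif any(_intersects(w0, w1, g0, g1) for g0, g1 in gaps):
            excl.add(w1, obs.window_len_min, "missing_data",
                     obs.seizure_index)
        else:
            kept.append(obs)
    return kept, excl


def observations_to_frame(observations: list[LabeledObservation]) -> pd.DataFrame:
    from .rates import FEATURE_NAMES

    df = pd.DataFrame(
        [o.feature.values for o in observations], columns=list(FEATURE_NAMES)
    )
    df.insert(0, "window_end_s", [o.feature.window_end_s for o in observations])
    df.insert(1, "window_start_s",
              [o.feature.window_start_s for o in observations])
    df["label"] = [o.label for o in observations]
    df["seizure_index"] = [o.seizure_index for o in observations]
    return df
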