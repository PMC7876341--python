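"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive results with different algorithms (explicit
loops, minute-resolution masks, direct moment formulas) so they share as
little code as possible with the implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- detector
def naive_detect_runs(rms, xabs, rms_mean, rms_sd, rect_mean, rect_sd,
                      fs, threshold_sd=5.0, min_duration_ms=6.0,
                      min_peaks=6, peak_threshold_sd=3.0, merge_gap_ms=10.0):
    """Sample-by-sample run scan + merge + peak count (pure loops)."""
    if rms_sd == 0:
        return []
    thr = rms_mean + threshold_sd * rms_sd
    runs = []
    in_run = False
    start = 0
    for i, v in enumerate(rms):
        if v > thr and not in_run:
            in_run, start = True, i
        elif v <= thr and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(rms)))
    gap = int(round(merge_gap_ms * fs / 1000.0))
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(r)
    min_len = min_duration_ms * fs / 1000.0
    peak_h = rect_mean + peak_threshold_sd * rect_sd
    out = []
    for i0, i1 in merged:
        if i1 - i0 < min_len:
            continue
        npk = 0
        for i in range(i0 + 1, i1 - 1):
            if (xabs[i] > xabs[i - 1] and xabs[i] > xabs[i + 1]
                    and xabs[i] >= peak_h):
                npk += 1
        if npk >= min_peaks:
            out.append((i0, i1))
    return out


# ------------------------------------------------------------- statistics
def naive_window_stats(x):
    """The 8 rate-feature statistics from first principles."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    # OLS slope against time in minutes
    t = [i / 60.0 for i in range(n)]
    tbar = sum(t) / n
    sxx = sum((ti - tbar) ** 2 for ti in t)
    sxy = sum((ti - tbar) * (v - mean) for ti, v in zip(t, x))
    slope = sxy / sxx

    def quantile(q):
        s = sorted(x)
        pos = q * (n - 1)
        lo = math.floor(pos)
        hi = math.ceil(pos)
        return s[lo] + (pos - lo) * (s[hi] - s[lo])

    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    kurt = m4 / m2 ** 2 - 3.0 if m2 > 0 else 0.0
    return {"MEAN": mean, "VAR": m2, "SLOPE": slope,
            "Q1": quantile(0.25), "Q2": quantile(0.5), "Q3": quantile(0.75),
            "SKEW": skew, "KURT": kurt}


# --------------------------------------------------------------- labeling
def naive_label(available_ends, window_len_min, onsets, offsets, duration):
    """Minute-mask re-derivation of the labeling rules.

    Returns (preictal: {end -> seizure index}, interictal: set of ends).
    """
    L = 60.0 * window_len_min
    zone, buff, post = 31 * 60.0, 60.0, 11 * 60.0
    ends = set(float(e) for e in available_ends)

    preictal = {}
    for k, onset in enumerate(onsets):
        e = math.floor((onset - buff) / 60.0) * 60.0
        if e not in ends:
            continue
        w0, w1 = e - L, e
        clash = False
        for j in range(len(onsets)):
            if j == k:
                continue
            if w0 < offsets[j] + post and onsets[j] - zone < w1:
                clash = True
        if not clash:
            preictal[e] = k

    # minute-resolution admissibility mask
    n_min = int(duration // 60)
    free = [True] * n_min
    for onset, offset in zip(onsets, offsets):
        for m in range(n_min):
            if m * 60.0 < offset + post and onset - zone < (m + 1) * 60.0:
                free[m] = False
    interictal = set()
    m = 0
    while m < n_min:
        if not free[m]:
            m += 1
            continue
        span_start = m
        while m < n_min and free[m]:
            m += 1
        span_len = m - span_start
        k = 0
        while (k + 1) * window_len_min <= span_len:
            e = (span_start + (k + 1) * window_len_min) * 60.0
            if e in ends:
                interictal.add(e)
            k += 1
    return preictal, interictal
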