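"""Simulation studies exercising the full pipeline end to end.

Each study generates synthetic patients under stated conditions, runs the
complete detection/rate/label/model/evaluation chain, and reports aggregate
operating characteristics:

* :func:`null_calibration_study` — no preictal effect; checks that held-out
  AUC centers on chance and the responder rule keeps its nominal error rate.
* :func:`ramp_recovery_study` — strong SOZ rate ramp; checks that the
  pipeline detects the effect and attributes it to the rate-slope feature.
* :func:`detector_fidelity_study` — known bursts embedded in 1/f noise;
  measures detector recall and precision.
* :func:`rate_conservation_check` — exact integer-count consistency of the
  sliding-window rate estimator.

Problem sizes default to desk scale (single CPU, minutes); every sampled
quantity is reproducible from the single ``seed`` argument.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import HFOEvent
from .detect import DetectorConfig, pseudo_prospective_detect
from .evaluation import feature_frequency, summarize_patient
from .model import run_patient
from .pipeline import RunConfig, simulate_patient_observations
from .rates import FEATURE_NAMES, compute_chfo_rate
from .synthetic import PreictalEffect, SimConfig, make_channel_map

__all__ = [
    "null_calibration_study",
    "ramp_recovery_study",
    "detector_fidelity_study",
    "rate_conservation_check",
]


def _derive(seed: int, *key) -> int:
    return int(np.random.SeedSequence([int(seed), *map(int, key)])
               .generate_state(1)[0] % 2**31)


def _patient_config(seed: int, effect: PreictalEffect, n_seizures: int,
                    duration_s: float, n_soz: int, n_out: int) -> RunConfig:
    return RunConfig(
        n_seizures=n_seizures,
        recording_duration_s=duration_s,
        min_seizure_gap_s=7200.0,
        sim=SimConfig(n_soz=n_soz, n_out=n_out, preictal_effect=effect),
        master_seed=seed,
    )


def _run_one_patient(cfg: RunConfig, n_repeats: int, n_perm: int):
    obs, _ = simulate_patient_observations(cfg)
    results = run_patient(obs, n_repeats, base_seed=cfg.master_seed)
    summary = summarize_patient(results, n_perm, seed=cfg.master_seed)
    return results, summary


def null_calibration_study(
    n_patients: int = 100,
    seed: int = 0,
    n_perm: int = 200,
    n_repeats: int = 10,
    n_seizures: int = 6,
    duration_s: float = 24.5 * 3600.0,
    n_soz: int = 4,
    n_out: int = 8,
) -> dict:
    """Type-I-error check: simulate patients with NO preictal effect.

    Returns per patient-window mean AUC / combined p / responder flag, plus
    the aggregate mean test AUC and the window-level responder-flag rate at
    the nominal alpha.
    """
    rows = []
    for pi in range(n_patients):
        cfg = _patient_config(_derive(seed, pi), PreictalEffect("none"),
                              n_seizures, duration_s, n_soz, n_out)
        results, summary = _run_one_patient(cfg, n_repeats, n_perm)
        for L, w in summary.windows.items():
            rows.append({"patient": pi, "window_len_min": L,
                         "mean_auc": w.mean_auc, "hm_p": w.hm_p,
                         "responder": w.responder,
                         "n_converged": w.n_converged})
    df = pd.DataFrame(rows)
    return {
        "table": df,
        "n_patient_windows": len(df),
        "mean_test_auc": float(df["mean_auc"].mean()),
        "responder_rate": float(df["responder"].mean()),
        "significant_p_rate": float((df["hm_p"] < 0.05).mean()),
        "convergence_rate": float(df["n_converged"].sum()
                                  / (len(df) * n_repeats)),
    }


def ramp_recovery_study(
    n_seeds: int = 10,
    seed: int = 0,
    magnitude: float = 3.0,
    horizon_min: float = 30.0,
    n_seizures: int = 12,
    duration_s: float = 26 * 3600.0,
    n_soz: int = 4,
    n_out: int = 8,
    n_repeats: int = 10,
    n_perm: int = 1000,
) -> dict:
    """Power/attribution check: linear SOZ rate ramp up to ``magnitude`` x
    baseline at onset.

    Per seed, reports the 30-min-window mean test AUC; across seeds, pools
    the models from significant responder patient-windows and ranks features
    by non-zero-coefficient frequency.
    """
    aucs_30 = []
    responder_flags = []
    sig_models = []
    effect = PreictalEffect("linear_ramp", horizon_min, magnitude)
    for si in range(n_seeds):
        cfg = _patient_config(_derive(seed, si, 7), effect, n_seizures,
                              duration_s, n_soz, n_out)
        results, summary = _run_one_patient(cfg, n_repeats, n_perm)
        aucs_30.append(summary.windows[30].mean_auc)
        responder_flags.append(summary.responder)
        for L, w in summary.windows.items():
            if L == 30 and w.responder:
                sig_models.extend(r.model for r in results
                                  if r.window_len_min == 30)
    freq = feature_frequency(sig_models) if sig_models else None
    out = {
        "mean_auc_30_per_seed": aucs_30,
        "n_seeds": n_seeds,
        "n_seeds_auc_ge_06": int(sum(a >= 0.6 for a in aucs_30)),
        "responder_rate": float(np.mean(responder_flags)),
        "feature_frequency": freq,
    }
    if freq is not None and len(freq):
        fmap = dict(zip(freq["feature"], freq["frequency"]))
        out["slope_soz_frequency"] = float(fmap["SLOPE-SOZ"])
        out["slope_soz_is_top"] = bool(
            fmap["SLOPE-SOZ"] >= max(fmap.values()) - 1e-12)
        out["slope_soz_median_sign"] = int(
            freq.set_index("feature").loc["SLOPE-SOZ", "median_sign"])
    return out


def _overlap_recall_precision(
    detected: list[HFOEvent], truth: list[HFOEvent]
) -> tuple[float, float]:
    """Greedy one-to-one interval matching by time overlap, per channel."""
    matched_truth: set[int] = set()
    tp = 0
    for d in detected:
        for i, t in enumerate(truth):
            if i in matched_truth or t.channel_id != d.channel_id:
                continue
            if d.start_s < t.end_s and t.start_s < d.end_s:
                matched_truth.add(i)
                tp += 1
                break
    recall = tp / len(truth) if truth else 1.0
    precision = tp / len(detected) if detected else 1.0
    return recall, precision


def detector_fidelity_study(
    n_seeds: int = 10,
    seed: int = 0,
    snr: float = 10.0,
    sampling_rate: float = 2048.0,
    duration_s: float = 900.0,
    n_channels: int = 3,
    n_bursts_per_channel: int = 34,
) -> dict:
    """Recall/precision of the causal detector on synthesized recordings.

    Ground-truth bursts are embedded only after the 10-min warm-up (the
    detector cannot emit events before it); matching is by interval overlap.
    """
    from .synthetic import synthesize_ieeg

    cm = make_channel_map(1, n_channels - 1)
    det_cfg = DetectorConfig()
    per_seed = []
    min_start = np.inf
    for si in range(n_seeds):
        rng = np.random.default_rng(_derive(seed, si, 13))
        truth = []
        for ch in cm.ids():
            # uniform burst starts with a minimum separation of 1 s
            usable = duration_s - det_cfg.background_len_s - 10.0
            starts = det_cfg.background_len_s + 5.0 + np.sort(
                rng.uniform(0, usable, n_bursts_per_channel))
            starts = starts[np.r_[True, np.diff(starts) > 1.0]]
            truth += [HFOEvent(ch, float(s), float(s + 0.05)) for s in starts]
        sim = SimConfig(sampling_rate=sampling_rate, burst_snr=snr,
                        rng_seed=_derive(seed, si, 17),
                        n_soz=1, n_out=n_channels - 1)
        seg = synthesize_ieeg(truth, cm, sim, duration_s)
        detected = pseudo_prospective_detect(seg, cm, det_cfg)
        r, p = _overlap_recall_precision(detected, truth)
        per_seed.append({"seed": si, "recall": r, "precision": p,
                         "n_truth": len(truth), "n_detected": len(detected)})
        if detected:
            min_start = min(min_start, min(d.start_s for d in detected))
    df = pd.DataFrame(per_seed)
    return {
        "table": df,
        "recall_min": float(df["recall"].min()),
        "precision_min": float(df["precision"].min()),
        "recall_mean": float(df["recall"].mean()),
        "precision_mean": float(df["precision"].mean()),
        "min_event_start_s": float(min_start),
    }


def rate_conservation_check(n_fixtures: int = 20, seed: int = 0) -> dict:
    """Exact-count consistency: rate x channel count vs integer counts."""
    max_err = 0.0
    for fi in range(n_fixtures):
        rng = np.random.default_rng(_derive(seed, fi, 23))
        n_soz, n_out = rng.integers(1, 5), rng.integers(1, 8)
        cm = make_channel_map(int(n_soz), int(n_out))
        duration = float(rng.integers(300, 1200))
        ids = cm.ids()
        n_ev = int(rng.integers(0, 400))
        events = [
            HFOEvent(ids[int(rng.integers(0, len(ids)))],
                     float(s), float(s) + 0.05)
            for s in rng.uniform(0, duration - 0.1, n_ev)
        ]
        events.sort(key=lambda e: e.start_s)
        series = compute_chfo_rate(events, cm, duration)
        starts = {"SOZ": np.sort([e.start_s for e in events
                                  if e.channel_id.startswith("SOZ")]),
                  "OUT": np.sort([e.start_s for e in events
                                  if e.channel_id.startswith("OUT")])}
        for g, n_ch in (("SOZ", n_soz), ("OUT", n_out)):
            counts = series.rate(g) * n_ch
            expected = (np.searchsorted(starts[g], series.times)
                        - np.searchsorted(starts[g], series.times - 60.0))
            max_err = max(max_err, float(np.abs(counts - expected).max()))
    return {"n_fixtures": n_fixtures, "max_abs_count_error": max_err}
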