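"""Predictive-performance assessment and responder classification.

Held-out discrimination is measured by ROC AUC (Mann-Whitney form).  Each
repeat's AUC is tested against chance by permuting the test labels (1,000
label randomizations by default, class counts preserved); the 10 repeats'
p-values for a window length are combined with their harmonic mean.  A
patient "responds" for a window length when the mean test AUC is >= 0.6 and
the combined p is < 0.05; a responder patient responds in at least one
window length.  No multiplicity correction is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

from .model import FittedModel, RepeatResult

__all__ = [
    "ROCResult",
    "BootstrapResult",
    "WindowSummary",
    "PatientSummary",
    "roc_auc",
    "bootstrap_pvalue",
    "harmonic_mean_p",
    "summarize_patient",
    "classify_responder",
    "feature_frequency",
    "responder_proportion_ci",
]

AUC_THRESHOLD = 0.6
ALPHA = 0.05


@dataclass(frozen=True)
class ROCResult:
    auc: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class BootstrapResult:
    observed_auc: float
    n_perm: int
    p_value: float


def _rank_auc(ranks: np.ndarray, pos: np.ndarray) -> float:
    n_pos = int(pos.sum())
    n_neg = ranks.size - n_pos
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """AUC as the Mann-Whitney statistic P(s_pos > s_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return ROCResult(_rank_auc(ranks, pos), n_pos, n_neg)


def bootstrap_pvalue(
    scores: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Permutation significance of an observed test AUC.

    Test labels are randomized ``n_perm`` times preserving class counts; the
    plus-one estimator p = (1 + #{AUC_perm >= AUC_obs}) / (n_perm + 1)
    guards against p = 0.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels).astype(bool)
    n = scores.size
    n_pos = int(pos.sum())
    if n_pos < 2 or n - n_pos < 2:
        warnings.warn("fewer than 2 observations in a class; permutation "
                      "p-value is unreliable")
    obs = roc_auc(scores, labels)
    ranks = rankdata(scores)
    rng = np.random.default_rng(seed)
    # random label assignments = random n_pos-subsets of the indices
    u = rng.random((n_perm, n))
    idx = np.argpartition(u, n_pos - 1, axis=1)[:, :n_pos]
    sums = ranks[idx].sum(axis=1)
    aucs = (sums - n_pos * (n_pos + 1) / 2.0) / (n_pos * (n - n_pos))
    p = (1.0 + int((aucs >= obs.auc - 1e-12).sum())) / (n_perm + 1.0)
    return BootstrapResult(obs.auc, n_perm, p)


def harmonic_mean_p(p_values) -> float:
    """Harmonic mean of p-values: n / sum(1/p).  No further correction."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    return float(p.size / np.sum(1.0 / p))


@dataclass(frozen=True)
class WindowSummary:
    window_len_min: int
    mean_auc: float
    hm_p: float
    n_repeats: int
    n_converged: int
    responder: bool


@dataclass
class PatientSummary:
    windows: dict[int, WindowSummary]
    auc_threshold: float = AUC_THRESHOLD
    alpha: float = ALPHA

    @property
    def responder(self) -> bool:
        return any(w.responder for w in self.windows.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "window_len_min": w.window_len_min,
                "mean_auc": w.mean_auc,
                "hm_p": w.hm_p,
                "n_repeats": w.n_repeats,
                "n_converged": w.n_converged,
                "responder": w.responder,
                "stars": "***" if w.hm_p < 0.001 else
                         "**" if w.hm_p < 0.01 else
                         "*" if w.hm_p < self.alpha else "",
            }
            for w in sorted(self.windows.values(),
                            key=lambda w: -w.window_len_min)
        ]
        return pd.DataFrame(rows)


def summarize_patient(
    results: list[RepeatResult],
    n_perm: int = 1000,
    seed: int = 0,
    auc_threshold: float = AUC_THRESHOLD,
    alpha: float = ALPHA,
) -> PatientSummary:
    """Mean AUC, harmonic-mean permutation p, and responder flag per window.

    Non-converged repeats contribute AUC 0.5 and p = 1 (chance performance
    by assignment).
    """
    by_window: dict[int, list[RepeatResult]] = {}
    for r in results:
        by_window.setdefault(r.window_len_min, []).append(r)
    windows = {}
    for L, reps in by_window.items():
        aucs, ps = [], []
        for r in reps:
            if r.model.converged:
                aucs.append(r.test_auc)
                ps.append(
                    bootstrap_pvalue(
                        r.test_scores, r.test_labels, n_perm,
                        seed=int(np.random.SeedSequence(
                            [seed, L, r.repeat]).generate_state(1)[0] % 2**31),
                    ).p_value
                )
            else:
                aucs.append(0.5)
                ps.append(1.0)
        mean_auc = float(np.mean(aucs))
        hm = harmonic_mean_p(ps)
        windows[L] = WindowSummary(
            L, mean_auc, hm, len(reps),
            sum(r.model.converged for r in reps),
            bool(mean_auc >= auc_threshold and hm < alpha),
        )
    return PatientSummary(windows, auc_threshold, alpha)


def classify_responder(summary: PatientSummary) -> dict:
    """Window-level responder flags plus the overall patient flag."""
    flags = {L: w.responder for L, w in summary.windows.items()}
    flags["any"] = summary.responder
    return flags


def feature_frequency(
    models: list[FittedModel], include_nonconverged: bool = False
) -> pd.DataFrame:
    """How often each feature's coefficient is non-zero across models.

    Non-converged (all-zero) models are excluded from the denominator by
    default.  Returns features ranked by descending frequency with the
    median coefficient and its sign.
    """
    scope = [m for m in models if include_nonconverged or m.converged]
    if not scope:
        warnings.warn("no converged models; empty feature ranking")
        return pd.DataFrame(
            columns=["feature", "frequency", "median_coef", "median_sign"]
        )
    coefs = np.array([m.coef for m in scope])
    names = scope[0].feature_names
    freq = (coefs != 0).mean(axis=0)
    med = np.median(coefs, axis=0)
    df = pd.DataFrame(
        {
            "feature": list(names),
            "frequency": freq,
            "median_coef": med,
            "median_sign": np.sign(med).astype(int),
        }
    )
    return (
        df.sort_values(["frequency", "feature"], ascending=[False, True])
        .reset_index(drop=True)
    )


def responder_proportion_ci(
    n_responders: int,
    n_patients: int,
    confidence: float = 0.95,
    method: str = "normal",
) -> tuple[int, int]:
    """Binomial confidence interval for the responder proportion, in whole
    percent.  Default is the normal-approximation (Wald) interval, clipped
    to [0, 100]%; ``method`` accepts any statsmodels ``proportion_confint``
    method (e.g. "wilson", "beta")."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not 0 <= n_responders <= n_patients:
        raise ValueError("n_responders must be in [0, n_patients]")
    lo, hi = proportion_confint(
        n_responders, n_patients, alpha=1 - confidence, method=method
    )
    lo = float(np.clip(lo, 0.0, 1.0))
    hi = float(np.clip(hi, 0.0, 1.0))
    return int(round(lo * 100)), int(round(hi * 100))
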