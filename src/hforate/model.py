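"""Patient-specific LASSO logistic classification of preictal windows.

For each feature-window length, observations are split 2/3 train : 1/3 test
(stratified within the preictal and interictal classes, at random rather
than chronologically), a LASSO logistic model is fitted with the penalty
chosen by k-fold cross-validated deviance (k = number of preictal training
observations, i.e. training seizures), and held-out discrimination is scored
by AUC.  The split/fit/test cycle is repeated 10 times per window length; a
fit whose selected model keeps no features is flagged non-converged and is
assigned chance performance downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._solver import deviance, lambda_grid, lambda_max, lasso_logistic_path
from .labeling import LabeledObservation
from .rates import FEATURE_NAMES

__all__ = [
    "TrainTestSplit",
    "FittedModel",
    "split_data",
    "fit_lasso_logistic",
    "predict_scores",
    "run_patient",
    "RepeatResult",
    "observations_to_xy",
]

log = logging.getLogger(__name__)

MIN_PREICTAL = 3  # cohort inclusion: at least three usable seizures


def observations_to_xy(
    observations: list[LabeledObservation],
) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([o.feature.values for o in observations])
    y = np.array([1.0 if o.label == "preictal" else 0.0 for o in observations])
    return X, y


@dataclass
class TrainTestSplit:
    train: list[LabeledObservation]
    test: list[LabeledObservation]
    split_seed: int
    stratification: dict[str, dict[str, int]]

    @property
    def n_train_preictal(self) -> int:
        return self.stratification["train"]["preictal"]


@dataclass
class FittedModel:
    """A fitted, standardized-scale LASSO logistic model.

    ``coef`` is on the standardized feature scale; ``center``/``scale``
    record the training standardization so raw features can be scored.
    ``converged`` is False iff the selected model has no active features
    (or the optimizer failed), in which case all 16 coefficients are 0.
    """

    intercept: float
    coef: np.ndarray
    lam: float
    k_inner: int
    converged: bool
    center: np.ndarray
    scale: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    dropped: tuple[str, ...] = ()

    def named_coef(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.coef.tolist()))


def split_data(
    observations: list[LabeledObservation], seed: int = 0
) -> TrainTestSplit:
    """Stratified random 2/3 train : 1/3 test split.

    The train count is round(2n/3) per class, clipped so each side keeps at
    least one observation of each class.  Deterministic per seed.
    """
    pre = [o for o in observations if o.label == "preictal"]
    inter = [o for o in observations if o.label == "interictal"]
    if len(pre) < MIN_PREICTAL:
        raise ValueError(
            f"fewer than {MIN_PREICTAL} preictal observations "
            f"({len(pre)}); patient does not meet the inclusion criterion"
        )
    if len(inter) < 2:
        raise ValueError("need at least 2 interictal observations")
    rng = np.random.default_rng(seed)
    train: list[LabeledObservation] = []
    test: list[LabeledObservation] = []
    strat: dict[str, dict[str, int]] = {"train": {}, "test": {}}
    for name, group in (("preictal", pre), ("interictal", inter)):
        idx = rng.permutation(len(group))
        n_train = int(np.clip(round(2 * len(group) / 3), 1, len(group) - 1))
        train.extend(group[i] for i in idx[:n_train])
        test.extend(group[i] for i in idx[n_train:])
        strat["train"][name] = n_train
        strat["test"][name] = len(group) - n_train
    return TrainTestSplit(train, test, seed, strat)


def fit_lasso_logistic(
    split: TrainTestSplit,
    seed: int = 0,
    n_lambda: int = 100,
    decades: float = 4.0,
    k_inner: int | None = None,
    selection: str = "min",
) -> FittedModel:
    """Fit LASSO logistic regression with inner cross-validated penalty choice.

    Features are standardized on the training data; constant features are
    dropped (their coefficients stay 0).  The penalty grid runs from the
    smallest all-zero penalty down ``decades`` decades; selection is the
    minimum mean cross-validated deviance ("min") or the one-standard-error
    rule ("1se").
    """
    X, y = observations_to_xy(split.train)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    active = scale > 0
    dropped = tuple(n for n, a in zip(FEATURE_NAMES, active) if not a)
    if dropped:
        log.info("dropping constant features: %s", ", ".join(dropped))
    scale_safe = np.where(active, scale, 1.0)
    Xs = (X - center) / scale_safe
    Xa = Xs[:, active]

    if k_inner is None:
        k_inner = split.n_train_preictal
    k = int(np.clip(k_inner, 2, min(int(y.sum()), int((1 - y).sum()))))
    lmax = lambda_max(Xa, y)
    coef_full = np.zeros(len(FEATURE_NAMES))
    if lmax <= 0 or Xa.shape[1] == 0:
        return FittedModel(float(np.log(y.mean() / (1 - y.mean()))), coef_full,
                           np.nan, k, False, center, scale_safe,
                           dropped=dropped)
    grid = lambda_grid(lmax, n_lambda, decades)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    dev = np.zeros((k, len(grid)))
    for fi, (tr, va) in enumerate(skf.split(Xa, y)):
        b0s, betas = lasso_logistic_path(Xa[tr], y[tr], grid)
        dev[fi] = deviance(b0s, betas, Xa[va], y[va])
    mean_dev = dev.mean(axis=0)
    if selection == "1se":
        se = dev.std(axis=0, ddof=1) / np.sqrt(k)
        best = int(np.argmin(mean_dev))
        ok = mean_dev <= mean_dev[best] + se[best]
        li = int(np.flatnonzero(ok)[0])  # largest admissible penalty
    else:
        li = int(np.argmin(mean_dev))  # ties -> largest penalty (first index)
    b0s, betas = lasso_logistic_path(Xa, y, grid[: li + 1])
    b0, beta = float(b0s[li]), betas[li]
    ok = np.all(np.isfinite(beta)) and np.isfinite(b0)
    converged = bool(ok and np.any(beta != 0))
    if not converged:
        beta = np.zeros_like(beta)
    coef_full[active] = beta
    return FittedModel(b0 if ok else 0.0, coef_full, float(grid[li]), k,
                       converged, center, scale_safe, dropped=dropped)


def predict_scores(
    model: FittedModel,
    observations: list[LabeledObservation] | np.ndarray,
) -> np.ndarray:
    """Class-1 (preictal) probabilities on raw-scale feature rows."""
    if isinstance(observations, np.ndarray):
        X = observations
    else:
        X, _ = observations_to_xy(observations)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    eta = model.intercept + ((X - model.center) / model.scale) @ model.coef
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))


@dataclass
class RepeatResult:
    """One cross-validation repeat: split seed, model, held-out evaluation."""

    window_len_min: int
    repeat: int
    model: FittedModel
    test_auc: float
    test_scores: np.ndarray
    test_labels: np.ndarray


def _derive_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_patient(
    observations_by_window: dict[int, list[LabeledObservation]],
    n_repeats: int = 10,
    base_seed: int = 0,
    **fit_kwargs,
) -> list[RepeatResult]:
    """Run the full split/fit/test design for one patient.

    10 seeded repeats for each available window length (up to 3 x 10 = 30
    models).  A window length with fewer than three preictal observations is
    skipped and logged.  Non-converged fits get the conservative assignment
    of a 0.5 test AUC (and p = 1 downstream).
    """
    from .evaluation import roc_auc

    results: list[RepeatResult] = []
    for L, obs in sorted(observations_by_window.items(), reverse=True):
        n_pre = sum(o.label == "preictal" for o in obs)
        if n_pre < MIN_PREICTAL:
            log.warning(
                "window length %d min skipped: %d preictal observations",
                L, n_pre,
            )
            continue
        for r in range(n_repeats):
            seed = _derive_seed(base_seed, L, r)
            split = split_data(obs, seed)
            model = fit_lasso_logistic(split, seed=seed, **fit_kwargs)
            Xte, yte = observations_to_xy(split.test)
            scores = predict_scores(model, Xte)
            auc = roc_auc(scores, yte).auc if model.converged else 0.5
            results.append(RepeatResult(L, r, model, auc, scores, yte))
    return results
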