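"""Population decoding, noise correlations, and correlation disruption.

Trial-type decoding trains a linear maximum-margin classifier (linear SVM)
per spatial bin on the z-scored activity of a random neuron subsample,
under stratified 10-fold cross-validation; held-out accuracy is averaged
over folds, bins, and repeated subsamples. Noise correlations are pairwise
Pearson correlations of trial-to-trial responses within a fixed trial type,
averaged across trial types; shuffling each neuron's trial order
independently within trial type destroys them while leaving every
single-neuron statistic untouched.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC


def _cv_accuracy_svm(X: np.ndarray, y: np.ndarray, cv: StratifiedKFold, C: float) -> float:
    """Stratified-CV accuracy of a linear SVM with fold-wise standardization.

    The per-feature mean/sd are fit on the training folds only and applied
    to the held-out fold (no leakage). Equivalent to a scaler+LinearSVC
    pipeline but without per-fold estimator-cloning overhead.
    """
    correct = 0
    for train, test in cv.split(X, y):
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        clf = LinearSVC(C=C, dual="auto", max_iter=5000)
        clf.fit((X[train] - mu) / sd, y[train])
        correct += int((clf.predict((X[test] - mu) / sd) == y[test]).sum())
    return correct / len(y)

from .types import BinnedActivity, DecodingCurve, NoiseCorrelationSummary, RunningTrace

logger = logging.getLogger(__name__)

__all__ = [
    "decode_trial_type",
    "decode_choice_from_running",
    "noise_correlations",
    "disrupt_correlations",
    "correlation_impact_on_decoding",
]

#: Subsample repetitions per population size: 40 for sizes <= 10, else 20.
def default_repetitions(size: int) -> int:
    return 40 if size <= 10 else 20


DEFAULT_SIZES = (5, 10, 25, 50, 75, 150, 200)


def _as_array(activity: BinnedActivity | np.ndarray) -> np.ndarray:
    arr = activity.activity if isinstance(activity, BinnedActivity) else np.asarray(activity)
    if arr.ndim != 3:
        raise ValueError("activity must be [neurons, trials, bins]")
    return arr


def decode_trial_type(
    activity: BinnedActivity | np.ndarray,
    labels,
    sizes: Sequence[int] = DEFAULT_SIZES,
    seed: int | None = None,
    *,
    n_folds: int = 10,
    n_repetitions: int | None = None,
    C: float = 1.0,
    return_per_bin: bool = False,
) -> DecodingCurve:
    """Cross-validated trial-type decoding versus population size.

    For each population size and repetition a uniform neuron subsample is
    drawn without replacement; per spatial bin, each neuron's activity is
    standardized (scaler fit on training folds only) and a linear SVM
    (``C`` fixed, default 1) predicts the trial type under stratified
    ``n_folds``-fold cross-validation. Accuracy is averaged over folds,
    bins, and repetitions. Sizes exceeding the available neurons are
    skipped with a warning. ``n_repetitions`` overrides the default
    schedule (40 repetitions for sizes of at most 10 neurons, 20 above).
    """
    arr = _as_array(activity)
    n_neurons, n_trials, n_bins = arr.shape
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    folds = min(n_folds, int(counts.min()))
    if folds < n_folds:
        warnings.warn(
            f"reduced folds from {n_folds} to {folds} (smallest class has "
            f"{int(counts.min())} trials)",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    accuracy: dict[int, float] = {}
    reps_used: dict[int, int] = {}
    per_bin: dict[int, np.ndarray] = {}
    for size in sizes:
        if size > n_neurons:
            warnings.warn(f"population size {size} > {n_neurons} neurons; skipped",
                          stacklevel=2)
            continue
        reps = n_repetitions if n_repetitions is not None else default_repetitions(size)
        rep_bin_acc = np.empty((reps, n_bins))
        for r in range(reps):
            sub = rng.choice(n_neurons, size=size, replace=False)
            cv = StratifiedKFold(
                n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
            )
            for b in range(n_bins):
                rep_bin_acc[r, b] = _cv_accuracy_svm(arr[sub, :, b].T, labels, cv, C)
        accuracy[size] = float(rep_bin_acc.mean())
        reps_used[size] = reps
        if return_per_bin:
            per_bin[size] = rep_bin_acc.mean(axis=0)

    return DecodingCurve(
        population_sizes=list(accuracy),
        accuracy=accuracy,
        n_repetitions=reps_used,
        n_folds=folds,
        per_bin_accuracy=per_bin if return_per_bin else None,
    )


def decode_choice_from_running(
    running: RunningTrace,
    choices,
    n_folds: int = 10,
    seed: int | None = None,
) -> np.ndarray:
    """Decode the reported choice from running kinematics, per spatial bin.

    A binomial generalized linear model per bin uses four predictors —
    pitch, roll, and yaw treadmill velocities plus lateral maze position —
    under stratified ``n_folds``-fold cross-validation. Returns held-out
    accuracy per bin; bins with all-constant predictors report chance (0.5)
    with a warning.
    """
    choices = np.asarray(choices)
    if len(np.unique(choices)) != 2:
        raise ValueError("both choices must be present")
    folds = min(n_folds, int(np.unique(choices, return_counts=True)[1].min()))
    rng = np.random.default_rng(seed)
    acc = np.empty(running.n_bins)
    for b in range(running.n_bins):
        X = np.column_stack(
            [running.pitch[:, b], running.roll[:, b], running.yaw[:, b],
             running.lateral[:, b]]
        )
        if np.allclose(X.std(axis=0), 0.0):
            warnings.warn(f"constant predictors at bin {b}; accuracy set to 0.5",
                          stacklevel=2)
            acc[b] = 0.5
            continue
        cv = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
        acc[b] = cross_val_score(clf, X, choices, cv=cv).mean()
    return acc


def _trial_type_groups(labels) -> dict[object, np.ndarray]:
    labels = np.asarray(labels)
    return {t: np.nonzero(labels == t)[0] for t in pd.unique(labels)}


def noise_correlations(
    activity: BinnedActivity | np.ndarray,
    labels,
    *,
    area: np.ndarray | None = None,
    mode: str = "per_bin",
    min_trials_per_type: int = 3,
) -> NoiseCorrelationSummary:
    """Pairwise Pearson noise correlations averaged across trial types.

    For each trial type the correlation of two neurons' trial-wise
    responses is computed per spatial bin and averaged over bins
    (``mode='per_bin'``), or over the per-bin mean-subtracted responses
    concatenated across bins (``mode='concat'``); type-wise coefficients
    are then averaged across trial types. Pairs involving a zero-variance
    neuron within a type are skipped (NaN) and logged. Area-pair means are
    unweighted means over qualifying pairs.
    """
    arr = _as_array(activity)
    if area is None and isinstance(activity, BinnedActivity):
        area = activity.area
    n_neurons, n_trials, n_bins = arr.shape
    groups = _trial_type_groups(labels)
    for t, idx in groups.items():
        if len(idx) < min_trials_per_type:
            raise ValueError(
                f"trial type {t!r} has {len(idx)} trials; need >= {min_trials_per_type}"
            )

    type_means = []
    for idx in groups.values():
        data = arr[:, idx, :]  # [neurons, type trials, bins]
        if mode == "per_bin":
            bin_mats = []
            for b in range(n_bins):
                x = data[:, :, b]
                sd = x.std(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = np.corrcoef(x)
                r[sd == 0, :] = np.nan
                r[:, sd == 0] = np.nan
                bin_mats.append(r)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                type_means.append(np.nanmean(bin_mats, axis=0))
        elif mode == "concat":
            centered = data - data.mean(axis=1, keepdims=True)
            flat = centered.reshape(n_neurons, -1)
            sd = flat.std(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.corrcoef(flat)
            r[sd == 0, :] = np.nan
            r[:, sd == 0] = np.nan
            type_means.append(r)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pairwise = np.nanmean(type_means, axis=0)
    np.fill_diagonal(pairwise, np.nan)

    iu = np.triu_indices(n_neurons, k=1)
    n_skipped = int(np.isnan(pairwise[iu]).sum())
    if n_skipped:
        logger.info("skipped %d pairs with zero-variance neurons", n_skipped)

    area = np.asarray(area) if area is not None else np.repeat("all", n_neurons)
    pair_means: dict[tuple[str, str], float] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    pair_area = np.stack([area[iu[0]], area[iu[1]]], axis=1)
    vals = pairwise[iu]
    for key in {tuple(sorted(p)) for p in map(tuple, pair_area)}:
        mask = np.array([tuple(sorted(p)) == key for p in map(tuple, pair_area)])
        v = vals[mask]
        ok = ~np.isnan(v)
        pair_means[key] = float(v[ok].mean()) if ok.any() else float("nan")
        pair_counts[key] = int(ok.sum())

    return NoiseCorrelationSummary(
        pairwise_r=pairwise,
        area_pair_means=pair_means,
        area_pair_counts=pair_counts,
        n_skipped_pairs=n_skipped,
    )


def disrupt_correlations(
    activity: BinnedActivity | np.ndarray,
    labels,
    seed: int | None = None,
):
    """Destroy noise correlations by per-neuron trial shuffling.

    Within each trial type, each neuron's trials are permuted independently.
    Each neuron's per-type trial mean and per-type response multiset are
    exactly preserved, so every single-neuron statistic (mean activity,
    auROC, selectivity, significance) is unchanged; only the across-neuron
    co-fluctuations are removed. Returns the same container type as the
    input.
    """
    arr = _as_array(activity).copy()
    rng = np.random.default_rng(seed)
    for idx in _trial_type_groups(labels).values():
        if len(idx) < 2:
            raise ValueError("need >= 2 trials per trial type to shuffle")
        for i in range(arr.shape[0]):
            arr[i, idx, :] = arr[i, idx[rng.permutation(len(idx))], :]
    if isinstance(activity, BinnedActivity):
        return BinnedActivity(
            activity=arr,
            area=activity.area,
            bin_edges=activity.bin_edges,
            trial_meta=activity.trial_meta,
        )
    return arr


def correlation_impact_on_decoding(
    activity: BinnedActivity | np.ndarray,
    labels,
    size: int = 200,
    seed: int | None = None,
    *,
    n_folds: int = 10,
    n_repetitions: int | None = None,
) -> float:
    """Intact minus disrupted trial-type decoding accuracy at one size.

    Decoding runs on the original activity and on a copy with noise
    correlations disrupted, with matched neuron subsamples and CV folds
    (same seed). A negative value means decoding improves once correlations
    are removed, the signature of information-limiting correlations.
    """
    arr = _as_array(activity)
    if size > arr.shape[0]:
        raise ValueError(f"size {size} exceeds available neurons ({arr.shape[0]})")
    disrupted = disrupt_correlations(arr, labels, seed=seed)
    kwargs = dict(sizes=[size], seed=seed, n_folds=n_folds, n_repetitions=n_repetitions)
    intact_acc = decode_trial_type(arr, labels, **kwargs).accuracy[size]
    disrupted_acc = decode_trial_type(disrupted, labels, **kwargs).accuracy[size]
    return float(intact_acc - disrupted_acc)
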