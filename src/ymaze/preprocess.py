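"""Fluorescence normalization, spatial binning, and trial selection.

These are the steps applied before every neural analysis: neuropil-corrected
dF/F with a running-percentile baseline, summation of deconvolved events
into 5-cm spatial bins along the long maze axis, restriction to correct
trials from high-performance periods, and per-trial-type subsampling to
equalize trial counts across conditions.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .types import BinnedActivity, FluorescenceTrace, SessionBehavior

logger = logging.getLogger(__name__)

__all__ = [
    "sliding_percentile",
    "compute_dff",
    "bin_by_position",
    "select_high_performance_trials",
    "subsample_trials",
]


def sliding_percentile(x: np.ndarray, window: int, q: float) -> np.ndarray:
    """Centered sliding percentile with edge truncation.

    At sample ``i`` the percentile is taken over
    ``x[max(0, i - w//2) : min(n, i + w//2 + 1)]`` with ``w = window``;
    linear-interpolation percentile throughout.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if window < 1:
        raise ValueError("window must be >= 1")
    half = window // 2
    out = np.empty(n)
    lo_edge = min(half, n)
    hi_edge = max(n - half, lo_edge)
    # Interior: full windows of length 2*half + 1, vectorized.
    if hi_edge > lo_edge:
        full = np.lib.stride_tricks.sliding_window_view(x, 2 * half + 1)
        out[lo_edge:hi_edge] = np.percentile(full, q, axis=1)
    for i in range(lo_edge):
        out[i] = np.percentile(x[: i + half + 1], q)
    for i in range(hi_edge, n):
        out[i] = np.percentile(x[i - half :], q)
    return out


def compute_dff(
    trace: FluorescenceTrace,
    neuropil_coeff: float = 0.7,
    baseline_percentile: float = 8.0,
    baseline_window_s: float = 60.0,
) -> np.ndarray:
    """Neuropil-corrected dF/F with a running-percentile baseline.

    The numerator is the neuropil-corrected trace
    ``F - neuropil_coeff * F_neuropil`` minus its own running 8th-percentile
    baseline (60-s centered window, truncated at the edges); the denominator
    is the same running-percentile baseline of the raw somatic trace.
    """
    n = len(trace.F)
    window = int(round(baseline_window_s * trace.fs))
    if n <= window:
        raise ValueError(
            f"trace length ({n} samples) must exceed the baseline window ({window} samples)"
        )
    corrected = trace.F - neuropil_coeff * trace.F_neuropil
    baseline_corrected = sliding_percentile(corrected, window, baseline_percentile)
    baseline_raw = sliding_percentile(trace.F, window, baseline_percentile)
    bad = baseline_raw <= 0
    if bad.any():
        raise ValueError(
            f"raw-fluorescence baseline nonpositive at {int(bad.sum())} samples "
            f"(first at index {int(np.argmax(bad))}); dF/F undefined"
        )
    dff = (corrected - baseline_corrected) / baseline_raw
    trace.dff = dff
    return dff


def bin_by_position(
    activity_ts: np.ndarray,
    position_ts: np.ndarray,
    trial_id: np.ndarray,
    bin_size_cm: float = 5.0,
    maze_length_cm: float = 230.0,
    *,
    area: np.ndarray | None = None,
    trial_meta: pd.DataFrame | None = None,
) -> BinnedActivity:
    """Sum per-frame activity into uniform spatial bins per trial.

    ``activity_ts`` is ``[neurons, frames]`` (a single neuron may be passed
    as 1-D), aligned frame-by-frame with ``position_ts`` (cm along the long
    maze axis) and ``trial_id``. Bins are half-open ``[lo, hi)``; frames
    outside ``[0, maze_length_cm)`` are dropped and counted in the log.
    Trials with no frames yield an all-zero row and a warning.
    """
    activity_ts = np.atleast_2d(np.asarray(activity_ts, dtype=float))
    position_ts = np.asarray(position_ts, dtype=float)
    trial_id = np.asarray(trial_id)
    if activity_ts.shape[1] != len(position_ts) or len(position_ts) != len(trial_id):
        raise ValueError("activity, position, and trial_id must be frame-aligned")
    n_bins = int(np.ceil(maze_length_cm / bin_size_cm))
    bin_edges = np.arange(n_bins + 1, dtype=float) * bin_size_cm

    bin_idx = np.floor(position_ts / bin_size_cm).astype(int)
    in_maze = (position_ts >= 0) & (bin_idx < n_bins)
    n_dropped = int((~in_maze).sum())
    if n_dropped:
        logger.info("dropped %d frames outside the maze extent", n_dropped)

    trials = pd.unique(trial_id)
    trial_pos = {t: k for k, t in enumerate(trials)}
    t_idx = np.array([trial_pos[t] for t in trial_id])

    n_neurons = activity_ts.shape[0]
    out = np.zeros((n_neurons, len(trials), n_bins))
    flat = t_idx[in_maze] * n_bins + bin_idx[in_maze]
    for i in range(n_neurons):
        np.add.at(out[i].reshape(-1), flat, activity_ts[i, in_maze])

    frames_per_trial = np.bincount(t_idx[in_maze], minlength=len(trials))
    if (frames_per_trial == 0).any():
        warnings.warn(
            f"{int((frames_per_trial == 0).sum())} trial(s) have no in-maze frames",
            stacklevel=2,
        )

    if trial_meta is None:
        trial_meta = pd.DataFrame(index=range(len(trials)))
    if area is None:
        area = np.repeat("unknown", n_neurons)
    return BinnedActivity(
        activity=out, area=np.asarray(area), bin_edges=bin_edges, trial_meta=trial_meta
    )


def select_high_performance_trials(
    session: SessionBehavior | np.ndarray,
    window: int = 10,
    threshold: float = 0.8,
    mode: str = "any",
) -> np.ndarray:
    """Indices of correct trials inside high-performance periods.

    A period qualifies when a ``window``-trial stretch has at least
    ``threshold`` fraction correct; this excludes the relearning dips after
    rule switches. Window anchoring modes:

    ``any``
        a trial qualifies if ANY full length-``window`` window containing
        it reaches the threshold (default);
    ``trailing``
        the window ends at the trial (truncated at the session start);
    ``centered``
        the window is centered on the trial (truncated at both edges).

    Only correct trials are ever returned.
    """
    correct = (
        session.correct if isinstance(session, SessionBehavior) else np.asarray(session)
    ).astype(bool)
    n = len(correct)
    if window < 1:
        raise ValueError("window must be >= 1")
    if n < window:
        raise ValueError(f"session has {n} trials, fewer than the window ({window})")
    qualifies = np.zeros(n, dtype=bool)
    c = correct.astype(float)
    if mode == "any":
        means = np.convolve(c, np.ones(window), mode="valid") / window
        for s in np.nonzero(means >= threshold)[0]:
            qualifies[s : s + window] = True
    elif mode == "trailing":
        for t in range(n):
            lo = max(0, t - window + 1)
            qualifies[t] = c[lo : t + 1].mean() >= threshold
    elif mode == "centered":
        half = window // 2
        for t in range(n):
            lo, hi = max(0, t - half), min(n, t + half + 1)
            qualifies[t] = c[lo:hi].mean() >= threshold
    else:
        raise ValueError(f"unknown window mode {mode!r}")
    return np.nonzero(qualifies & correct)[0]


def subsample_trials(
    labels: Sequence | np.ndarray,
    n_per_type: int,
    types: Sequence | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Draw exactly ``n_per_type`` trials of each type, without replacement.

    ``labels`` assigns a trial type per trial (e.g. the cue on correct
    trials of one rule). Returns sorted positional indices; deterministic
    given ``seed``. The standard design subsamples to 30 trials per type
    for two-type comparisons and 15 per type (60 overall) when all four
    cue-choice combinations are analyzed together.
    """
    labels = np.asarray(labels)
    if types is None:
        types = sorted(pd.unique(labels).tolist())
    rng = np.random.default_rng(seed)
    picked = []
    for t in types:
        idx = np.nonzero(labels == t)[0]
        if len(idx) < n_per_type:
            raise ValueError(
                f"trial type {t!r} has only {len(idx)} trials, need {n_per_type}"
            )
        picked.append(rng.choice(idx, size=n_per_type, replace=False))
    return np.sort(np.concatenate(picked))
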