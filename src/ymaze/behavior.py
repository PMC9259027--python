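"""Behavioral performance metrics.

All metrics exclude visually guided trials by default (guided trials are
correct by construction), and are computed per session; cross-session
inference goes through :mod:`ymaze.hb`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from dataclasses import dataclass

from .types import SessionBehavior, TrialRecord


@dataclass
class SwitchAlignedCurve:
    """Mean performance at trial offsets relative to rule switches."""

    offsets: np.ndarray
    mean_performance: np.ndarray
    n_switches: int


NOT_REACHED = -1  # sentinel for sessions_to_criterion


def _filter_trials(
    trials: Iterable[TrialRecord], include_guided: bool
) -> list[TrialRecord]:
    return [t for t in trials if include_guided or not t.guided]


def fraction_correct(
    trials: Iterable[TrialRecord], include_guided: bool = False
) -> float:
    """Fraction of trials with a correct choice. Chance is 0.5."""
    kept = _filter_trials(trials, include_guided)
    if not kept:
        raise ValueError("no trials left after filtering guided trials")
    return float(np.mean([t.correct for t in kept]))


def delta_fraction_correct(
    session: SessionBehavior, target: str, include_guided: bool = False
) -> float:
    """Fraction correct on inhibition trials minus on control-spot trials."""
    kept = _filter_trials(session.trials, include_guided)
    target_trials = [t for t in kept if t.laser_target == target]
    control_trials = [t for t in kept if t.laser_target == "control"]
    if not target_trials:
        raise ValueError(f"no trials with laser target {target!r}")
    if not control_trials:
        raise ValueError("no control trials in session")
    return fraction_correct(target_trials, include_guided=True) - fraction_correct(
        control_trials, include_guided=True
    )


def signed_choice_bias(
    session: SessionBehavior, target: str = "none", include_guided: bool = False
) -> float:
    """Signed choice bias for one laser target.

    ``(FracCorr_left - FracCorr_right) / (FracCorr_left + FracCorr_right)``
    where ``FracCorr_side`` is the fraction correct among trials whose
    rewarded side is that side. +1/-1 means the subject only chose
    left/right.
    """
    kept = [
        t
        for t in _filter_trials(session.trials, include_guided)
        if t.laser_target == target
    ]
    by_side = {}
    for side in ("left", "right"):
        side_trials = [t for t in kept if t.correct_side == side]
        if not side_trials:
            raise ValueError(f"no trials with correct_side {side!r} for target {target!r}")
        by_side[side] = float(np.mean([t.correct for t in side_trials]))
    denom = by_side["left"] + by_side["right"]
    if denom == 0:
        raise ValueError("no correct responses on either side; bias undefined")
    return (by_side["left"] - by_side["right"]) / denom


def sessions_to_criterion(
    sessions: Sequence[SessionBehavior],
    task_kind: str,
    *,
    delay_reached: Sequence[bool] | None = None,
    max_guided_fraction: float = 0.2,
) -> int:
    """1-based index of the first session meeting the expert criteria.

    Criteria per session: at most 20% guided trials and average fraction
    correct (all trials, including guided and post-switch periods) of at
    least 70% for the switching task or 85% for the simple and delay tasks.
    The delay task additionally requires the full delay length, supplied as
    a per-session boolean in ``delay_reached``. Returns ``NOT_REACHED`` if
    no session qualifies.
    """
    if not sessions:
        raise ValueError("empty session list")
    threshold = 0.70 if task_kind == "switching" else 0.85
    if task_kind == "delay" and delay_reached is None:
        raise ValueError("delay task requires per-session delay_reached flags")
    for i, s in enumerate(sessions):
        guided_frac = float(np.mean(s.guided))
        frac = float(np.mean(s.correct))
        ok = guided_frac <= max_guided_fraction and frac >= threshold
        if task_kind == "delay":
            ok = ok and bool(delay_reached[i])
        if ok:
            return i + 1
    return NOT_REACHED


def switch_aligned_performance(
    sessions: Sequence[SessionBehavior] | SessionBehavior, window: int
) -> SwitchAlignedCurve:
    """Mean correctness around rule switches, offset 0 = first post-switch trial.

    Offsets run from ``-window`` to ``+window``; per switch, offsets that
    fall outside the session are dropped and the average is taken over the
    data available at each offset.
    """
    if isinstance(sessions, SessionBehavior):
        sessions = [sessions]
    offsets = np.arange(-window, window + 1)
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets))
    n_switches = 0
    for s in sessions:
        correct = s.correct.astype(float)
        for sw in s.rule_switch_trials():
            n_switches += 1
            idx = sw + offsets
            valid = (idx >= 0) & (idx < s.n_trials)
            sums[valid] += correct[idx[valid]]
            counts[valid] += 1
    if n_switches == 0:
        raise ValueError("no rule switches in the provided sessions")
    with np.errstate(invalid="ignore"):
        mean_perf = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SwitchAlignedCurve(
        offsets=offsets, mean_performance=mean_perf, n_switches=n_switches
    )
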