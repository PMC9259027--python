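"""Single-neuron trial-type selectivity.

Selectivity is quantified per neuron and spatial bin as the auROC between
the activity distributions of two trial types, with the unsigned index
``2 * |auROC - 0.5|`` in [0, 1]. Significance uses a permutation null: the
index is recomputed under label shuffles, and a bin is significant when the
probability of drawing the observed value from the shuffled distribution
falls below alpha (0.01 with 100 shuffles: the observed value must exceed
every shuffle).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import subsample_trials
from .types import (
    BinnedActivity,
    SegmentSpec,
    SegmentSummary,
    SelectivityProfile,
)

__all__ = [
    "auroc_per_bin",
    "selectivity_index",
    "shuffle_significance",
    "compute_selectivity_profile",
    "segment_summaries",
    "categorize_across_rules",
]


def _as_array(activity: BinnedActivity | np.ndarray) -> np.ndarray:
    arr = activity.activity if isinstance(activity, BinnedActivity) else activity
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:  # [trials, bins] for a single neuron
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("activity must be [neurons, trials, bins]")
    return arr


def _check_labels(labels, n_trials: int) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if len(labels) != n_trials:
        raise ValueError("labels must have one entry per trial")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present in labels")
    return labels


def _auroc_from_ranks(ranks: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """auROC from per-(neuron, bin) midranks over trials (Mann-Whitney)."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[:, labels, :].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def auroc_per_bin(
    activity: BinnedActivity | np.ndarray, labels
) -> np.ndarray:
    """auROC per neuron and spatial bin for a binary trial partition.

    The auROC is the probability that a random positive-class trial has
    higher activity than a random negative-class trial, with ties counted
    half (Mann-Whitney convention) — important for deconvolved data, which
    is zero in many bins.
    """
    arr = _as_array(activity)
    labels = _check_labels(labels, arr.shape[1])
    ranks = rankdata(arr, axis=1)
    # a single-neuron 2-D input still returns a [1, bins] array
    return _auroc_from_ranks(ranks, labels)


def selectivity_index(auroc: np.ndarray | float) -> np.ndarray | float:
    """Unsigned trial-type selectivity ``2 * |auROC - 0.5|``."""
    a = np.asarray(auroc, dtype=float)
    if ((a < 0) | (a > 1)).any():
        raise ValueError("auROC values must lie in [0, 1]")
    out = 2.0 * np.abs(a - 0.5)
    return float(out) if np.isscalar(auroc) else out


def shuffle_significance(
    activity: BinnedActivity | np.ndarray,
    labels,
    n_shuffles: int = 100,
    alpha: float = 0.01,
    seed: int | None = None,
    *,
    per_neuron: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation test of the selectivity index per neuron and bin.

    Returns ``(p, significant)`` arrays of shape ``[neurons, bins]``. The
    add-one estimator ``p = (1 + #{shuffle >= observed}) / (1 + n_shuffles)``
    never reaches zero; with 100 shuffles, ``p < 0.01`` means the observed
    index beats all shuffles. By default one label permutation per shuffle
    is applied to all neurons jointly, preserving cross-neuron structure
    within a shuffle; ``per_neuron=True`` permutes independently per neuron.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    arr = _as_array(activity)
    n_neurons, n_trials, n_bins = arr.shape
    labels = _check_labels(labels, n_trials)
    rng = np.random.default_rng(seed)
    ranks = rankdata(arr, axis=1)
    obs = selectivity_index(_auroc_from_ranks(ranks, labels))
    exceed = np.zeros((n_neurons, n_bins), dtype=int)
    for _ in range(n_shuffles):
        if per_neuron:
            perm = np.argsort(rng.random((n_neurons, n_trials)), axis=1)
            shuf_ranks = np.take_along_axis(ranks, perm[:, :, None], axis=1)
            sel = selectivity_index(_auroc_from_ranks(shuf_ranks, labels))
        else:
            perm = rng.permutation(n_trials)
            sel = selectivity_index(_auroc_from_ranks(ranks, labels[perm]))
        exceed += sel >= obs
    p = (1.0 + exceed) / (1.0 + n_shuffles)
    return p, p < alpha


def compute_selectivity_profile(
    activity: BinnedActivity,
    labels,
    n_shuffles: int = 100,
    alpha: float = 0.01,
    seed: int | None = None,
    **kwargs,
) -> SelectivityProfile:
    """auROC, selectivity index, and permutation significance in one pass."""
    auroc = auroc_per_bin(activity, labels)
    p, sig = shuffle_significance(
        activity, labels, n_shuffles=n_shuffles, alpha=alpha, seed=seed, **kwargs
    )
    return SelectivityProfile(
        auroc=auroc,
        selectivity=selectivity_index(auroc),
        p_shuffle=p,
        significant=sig,
        alpha=alpha,
        mean_activity=activity.activity.mean(axis=1),
        area=activity.area,
    )


def segment_summaries(
    profile: SelectivityProfile,
    bin_edges: np.ndarray,
    segments: SegmentSpec | None = None,
) -> SegmentSummary:
    """Reduce per-bin statistics to maze segments.

    Per neuron: unweighted mean activity and mean selectivity over the bins
    whose centers fall in the segment. Per area: the fraction of selective
    neurons is computed per bin (share of neurons significant at that bin)
    and then averaged over the segment's bins.
    """
    segments = segments or SegmentSpec()
    area = (
        profile.area
        if profile.area is not None
        else np.repeat("all", profile.auroc.shape[0])
    )
    per_neuron_rows = []
    per_area_rows = []
    for name in segments.segments:
        mask = segments.bin_mask(name, bin_edges)
        mean_sel = profile.selectivity[:, mask].mean(axis=1)
        mean_act = (
            profile.mean_activity[:, mask].mean(axis=1)
            if profile.mean_activity is not None
            else np.full(len(mean_sel), np.nan)
        )
        for i in range(len(mean_sel)):
            per_neuron_rows.append(
                {
                    "neuron": i,
                    "area": area[i],
                    "segment": name,
                    "mean_activity": mean_act[i],
                    "mean_selectivity": mean_sel[i],
                }
            )
        for a in pd.unique(area):
            sel_a = profile.significant[area == a][:, mask]
            frac_per_bin = sel_a.mean(axis=0)  # share of neurons, per bin
            per_area_rows.append(
                {
                    "area": a,
                    "segment": name,
                    "fraction_selective": float(frac_per_bin.mean()),
                    "mean_selectivity": float(
                        profile.selectivity[area == a][:, mask].mean()
                    ),
                    "mean_activity": float(mean_act[area == a].mean()),
                    "n_neurons": int((area == a).sum()),
                }
            )
    return SegmentSummary(
        per_neuron=pd.DataFrame(per_neuron_rows),
        per_area=pd.DataFrame(per_area_rows),
    )


def _significant_runs(sig: np.ndarray, run_length: int) -> list[tuple[int, int]]:
    """Start/stop (half-open) of runs of True at least run_length long."""
    runs = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        elif not s and start is not None:
            if i - start >= run_length:
                runs.append((start, i))
            start = None
    if start is not None and len(sig) - start >= run_length:
        runs.append((start, len(sig)))
    return runs


def categorize_across_rules(
    activity: BinnedActivity,
    n_per_type: int = 15,
    run_length: int = 3,
    n_shuffles: int = 100,
    alpha: float = 0.01,
    seed: int | None = None,
) -> pd.DataFrame:
    """Categorize neurons by selectivity across both rules.

    Within each rule, left-vs-right choice auROC plus permutation test per
    bin; a neuron is selective within a rule if it has at least
    ``run_length`` consecutive significant bins, with the rule's direction
    (preferred choice) taken as the majority of ``sign(auROC - 0.5)`` over
    significant run bins. Categories: ``single_trial_type`` (selective in
    one rule only), ``choice`` (both rules, same choice), ``cue`` (both
    rules, opposite choices — i.e. following the cue), ``complex``
    (conflicting directions within a rule), ``none``. Trials are subsampled
    to ``n_per_type`` per cue-choice combination first (15 each, 60 total,
    matching the two-type analyses' 30 per type).
    """
    meta = activity.trial_meta
    for col in ("cue", "rule", "choice"):
        if col not in meta.columns:
            raise ValueError(f"trial_meta lacks required column {col!r}")
    type_label = meta["cue"].astype(str) + "|" + meta["rule"].astype(str)
    if type_label.nunique() != 4:
        raise ValueError("all four cue-rule trial types must be present")
    keep = subsample_trials(type_label.to_numpy(), n_per_type, seed=seed)
    sub = activity.select_trials(keep)

    rng = np.random.default_rng(seed)
    per_rule: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    directions: dict[str, np.ndarray] = {}
    for rule in ("A", "B"):
        in_rule = (sub.trial_meta["rule"] == rule).to_numpy()
        arr = sub.activity[:, in_rule, :]
        labels = (sub.trial_meta.loc[in_rule, "choice"] == "right").to_numpy()
        auroc = auroc_per_bin(arr, labels)
        _, sig = shuffle_significance(
            arr, labels, n_shuffles=n_shuffles, alpha=alpha,
            seed=int(rng.integers(2**31)),
        )
        n_neurons = arr.shape[0]
        selective = np.zeros(n_neurons, dtype=bool)
        direction = np.zeros(n_neurons)  # +1 right, -1 left, 0 conflict/none
        for i in range(n_neurons):
            runs = _significant_runs(sig[i], run_length)
            if not runs:
                continue
            selective[i] = True
            signs = []
            for start, stop in runs:
                bins = np.arange(start, stop)
                signs.extend(np.sign(auroc[i, bins] - 0.5)[sig[i, bins]])
            signs = np.asarray(signs)
            pos, neg = (signs > 0).sum(), (signs < 0).sum()
            if pos and neg:
                direction[i] = 0.0  # opposite choices at different positions
            else:
                direction[i] = 1.0 if pos else -1.0
        per_rule[rule] = (selective, sig)
        directions[rule] = direction

    sel_a, sel_b = per_rule["A"][0], per_rule["B"][0]
    dir_a, dir_b = directions["A"], directions["B"]
    categories = []
    for i in range(len(sel_a)):
        if sel_a[i] and dir_a[i] == 0 or sel_b[i] and dir_b[i] == 0:
            cat = "complex"
        elif sel_a[i] and sel_b[i]:
            cat = "choice" if dir_a[i] == dir_b[i] else "cue"
        elif sel_a[i] or sel_b[i]:
            cat = "single_trial_type"
        else:
            cat = "none"
        categories.append(cat)

    def _dir_name(d: float) -> str:
        return {1.0: "right", -1.0: "left"}.get(d, "")

    return pd.DataFrame(
        {
            "neuron": np.arange(len(sel_a)),
            "area": activity.area,
            "category": categories,
            "selective_rule_A": sel_a,
            "selective_rule_B": sel_b,
            "direction_rule_A": [_dir_name(d) if s else "" for d, s in zip(dir_a, sel_a)],
            "direction_rule_B": [_dir_name(d) if s else "" for d, s in zip(dir_b, sel_b)],
        }
    )
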