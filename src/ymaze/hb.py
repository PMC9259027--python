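"""Hierarchical bootstrap estimation and testing.

Statistics are reported as the mean with an SEM defined as the standard
deviation of the means of bootstrap-resampled datasets (1000 resamples by
default). Resampling respects the data hierarchy: draw groups (sessions,
pooled across mice) with replacement, then units (trials or neurons) with
replacement within each drawn group. Two distributions are compared by the
smaller of P(A > B) and P(A < B), doubled for a two-tailed p value.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .types import BootstrapResult

__all__ = ["hierarchical_bootstrap", "bootstrap_p", "bonferroni"]


def _is_leaf(node) -> bool:
    if isinstance(node, np.ndarray):
        return node.ndim == 1
    return bool(node) and np.isscalar(node[0])


def _leaves(node) -> list[np.ndarray]:
    if _is_leaf(node):
        return [np.asarray(node, dtype=float)]
    out = []
    for child in node:
        out.extend(_leaves(child))
    return out


def _resample(node, rng: np.random.Generator) -> np.ndarray:
    if _is_leaf(node):
        arr = np.asarray(node, dtype=float)
        if len(arr) == 0:
            raise ValueError("empty group encountered during resampling")
        return arr[rng.integers(0, len(arr), len(arr))]
    if len(node) == 0:
        raise ValueError("empty group encountered during resampling")
    idx = rng.integers(0, len(node), len(node))
    return np.concatenate([_resample(node[i], rng) for i in idx])


def hierarchical_bootstrap(
    data,
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    levels: str = "auto",
    name: str = "mean",
) -> BootstrapResult:
    """Bootstrap a statistic over nested groups.

    ``data`` is a flat 1-D array (single level), a sequence of 1-D arrays
    (groups -> units, e.g. sessions -> trials or sessions -> neurons), or a
    deeper nesting of sequences. Each resample draws groups with
    replacement at the top level, then units with replacement within each
    drawn group (resample sizes equal the original sizes); the statistic is
    evaluated on the pooled resampled values. ``sem`` on the result is the
    SD of the ``n_boot`` resampled statistics.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    pooled = np.concatenate(_leaves(data))
    if len(pooled) == 0:
        raise ValueError("no observations in data")
    rng = np.random.default_rng(seed)
    boot = np.array([float(statistic(_resample(data, rng))) for _ in range(n_boot)])
    if levels == "auto":
        depth = 1
        node = data
        while not _is_leaf(node):
            depth += 1
            node = node[0]
        levels = "->".join(["groups"] * (depth - 1) + ["units"]) if depth > 1 else "units"
    return BootstrapResult(
        statistic_name=name,
        point_estimate=float(statistic(pooled)),
        boot_means=boot,
        levels=levels,
    )


def bootstrap_p(
    dist_a: np.ndarray | BootstrapResult,
    dist_b: np.ndarray | BootstrapResult | float = 0.0,
) -> float:
    """Doubled one-sided bootstrap p value for A versus B.

    ``p = 2 * min(P(A > B), P(A < B))``, with the tail probability floored
    at ``1 / n`` (so the smallest reportable p is ``2 / n``) and the result
    capped at 1. ``dist_b`` may be a bootstrap distribution (compared over
    paired resample draws, or all pairs when lengths differ) or a scalar
    reference such as 0.
    """
    a = np.asarray(
        dist_a.boot_means if isinstance(dist_a, BootstrapResult) else dist_a,
        dtype=float,
    )
    if len(a) == 0:
        raise ValueError("empty bootstrap distribution")
    if isinstance(dist_b, BootstrapResult):
        dist_b = dist_b.boot_means
    if np.isscalar(dist_b):
        gt = float(np.mean(a > dist_b))
        lt = float(np.mean(a < dist_b))
        n = len(a)
    else:
        b = np.asarray(dist_b, dtype=float)
        if len(b) == 0:
            raise ValueError("empty bootstrap distribution")
        if len(a) == len(b):
            gt = float(np.mean(a > b))
            lt = float(np.mean(a < b))
            n = len(a)
        else:
            diff = a[:, None] - b[None, :]
            gt = float(np.mean(diff > 0))
            lt = float(np.mean(diff < 0))
            n = diff.size
    p = 2.0 * max(min(gt, lt), 1.0 / n)
    return min(p, 1.0)


def bonferroni(p_values: Sequence[float] | np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``p_adj = min(1, m * p)``."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of comparisons")
    return np.minimum(1.0, m * p)
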