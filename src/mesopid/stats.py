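"""Condition-level statistics: permutation tests and Hedges' g.

Per-dataset summary metrics (fitted correlation length, effective
information lengths, long-path proportions) are compared between the
spontaneous and stimulated conditions with a two-sample permutation test
on the difference of group means, plus the small-sample-corrected
standardized effect size (Hedges' g). With the typical handful of
recordings per condition the relabeling space is small, so the test
enumerates it exhaustively when feasible and falls back to Monte Carlo
with add-one smoothing otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

EXHAUSTIVE_LIMIT = 100_000


def _as_groups(group_a, group_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    return a, b


def permutation_test(
    group_a,
    group_b,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "two_sided",
) -> tuple[float, str]:
    """Two-sample permutation p-value on the difference of means.

    Enumerates all relabelings when C(n_a + n_b, n_a) <= 100,000 (exact
    fraction); otherwise draws ``n_perm`` random relabelings and reports
    the add-one-smoothed Monte Carlo estimate. Returns ``(p, mode)``.
    """
    if alternative != "two_sided":
        raise ValueError("only two-sided tests are implemented")
    a, b = _as_groups(group_a, group_b)
    pooled = np.concatenate([a, b])
    n_a, n_total = a.size, a.size + b.size
    observed = abs(a.mean() - b.mean())
    total_sum = pooled.sum()

    def diff_from_sum_a(sum_a: np.ndarray) -> np.ndarray:
        return sum_a / n_a - (total_sum - sum_a) / (n_total - n_a)

    if comb(n_total, n_a) <= EXHAUSTIVE_LIMIT:
        sums_a = np.fromiter(
            (pooled[list(idx)].sum() for idx in combinations(range(n_total), n_a)),
            dtype=float,
        )
        null = np.abs(diff_from_sum_a(sums_a))
        p = float((null >= observed - 1e-12).sum() / null.size)
        return p, "exhaustive"

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:n_a].mean() - perm[n_a:].mean()) >= observed - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(p), "monte_carlo"


def hedges_g(group_a, group_b) -> float:
    """Hedges' g (a-minus-b orientation) with small-sample correction.

    g = J * (mean_a - mean_b) / s_pooled, with the pooled SD from the
    two sample variances and J = 1 - 3 / (4(n_a + n_b) - 9).
    """
    a, b = _as_groups(group_a, group_b)
    n_a, n_b = a.size, b.size
    pooled_var = (
        (n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)
    ) / (n_a + n_b - 2)
    if pooled_var <= 0:
        raise ZeroDivisionError("zero pooled variance: effect size undefined")
    j = 1.0 - 3.0 / (4.0 * (n_a + n_b) - 9.0)
    return float(j * (a.mean() - b.mean()) / np.sqrt(pooled_var))


@dataclass(frozen=True)
class GroupComparison:
    """Condition contrast (stimulated minus spontaneous) for one metric."""

    metric_name: str
    mean_difference: float
    p_value: float
    hedges_g: float
    n_stimulated: int
    n_spontaneous: int
    mode: str
    n_permutations: int


def compare_conditions(
    per_dataset_metrics: pd.DataFrame,
    metric_name: str,
    n_perm: int = 10_000,
    seed: int = 0,
    condition_column: str = "condition",
) -> GroupComparison:
    """Stimulated-vs-spontaneous contrast of a per-dataset metric.

    ``per_dataset_metrics`` holds one row per dataset with a condition
    label ('spontaneous' or 'stimulated') and the metric column. The
    contrast is oriented stimulated minus spontaneous.
    """
    if metric_name not in per_dataset_metrics.columns:
        raise ValueError(f"missing metric column {metric_name!r}")
    labels = per_dataset_metrics[condition_column]
    stim = per_dataset_metrics.loc[labels == "stimulated", metric_name].to_numpy(float)
    spont = per_dataset_metrics.loc[labels == "spontaneous", metric_name].to_numpy(float)
    if stim.size < 2 or spont.size < 2:
        raise ValueError("both conditions need at least 2 datasets")
    p, mode = permutation_test(stim, spont, n_perm=n_perm, seed=seed)
    try:
        g = hedges_g(stim, spont)
    except ZeroDivisionError:
        g = 0.0 if stim.mean() == spont.mean() else np.nan
    return GroupComparison(
        metric_name=metric_name,
        mean_difference=float(stim.mean() - spont.mean()),
        p_value=p,
        hedges_g=g,
        n_stimulated=int(stim.size),
        n_spontaneous=int(spont.size),
        mode=mode,
        n_permutations=n_perm,
    )
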