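"""Time-delayed mutual information and its partial information decomposition.

For a pair of binary neurons the past joint state U = (X_t, Y_t) and the
future joint state V = (X_{t+tau}, Y_{t+tau}) define a 16-outcome joint
distribution. The time-delayed mutual information (TDMI) I(U; V) is split
into redundant (RI), synergistic (SI) and unique (UI_X, UI_Y) components
using the minimum-mutual-information (MMI) redundancy function:

    RI   = min(i_x, i_y)          with  i_x = I(X_t; V),  i_y = I(Y_t; V)
    UI_X = i_x - RI,  UI_Y = i_y - RI
    SI   = TDMI - max(i_x, i_y)

All four components are non-negative (SI because joint information can
never be less than single-source information) and by construction one of
the unique terms is always zero. All quantities are in bits (base-2 logs).

Estimation is plug-in (maximum likelihood) on the empirical 16-cell
frequencies, with no pseudocounts; finite-sample bias is handled
downstream by the null-model z-scoring stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .population import NeuronPopulation

_NEG_TOL = 1e-9  # treat tiny negative float residue as zero


@dataclass(frozen=True)
class JointDistribution:
    """Joint distribution of (X_t, Y_t, X_{t+tau}, Y_{t+tau}).

    ``probs`` is a (2, 2, 2, 2) array indexed ``[x, y, x1, y1]``.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (2, 2, 2, 2):
            raise ValueError("probs must have shape (2, 2, 2, 2)")
        if p.min() < 0:
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    def as_uv(self) -> np.ndarray:
        """(4, 4) matrix over u = 2x+y (rows) and v = 2x1+y1 (columns)."""
        return self.probs.reshape(4, 4)


def _mi_bits(p: np.ndarray) -> float:
    """Mutual information (bits) of a 2-D joint probability table."""
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    mask = p > 0
    ratio = p[mask] / (pa @ pb)[mask]
    return float(np.sum(p[mask] * np.log2(ratio)))


def estimate_joint(
    x_series: np.ndarray, y_series: np.ndarray, tau: int = 1
) -> JointDistribution:
    """Plug-in joint of (X_t, Y_t, X_{t+tau}, Y_{t+tau}) over aligned frames."""
    x = np.asarray(x_series, dtype=np.int64)
    y = np.asarray(y_series, dtype=np.int64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be equal-length 1-D arrays")
    if tau < 1:
        raise ValueError("tau must be a positive number of frames")
    if x.size <= tau:
        raise ValueError(f"series length {x.size} must exceed tau={tau}")
    code = (
        8 * x[:-tau] + 4 * y[:-tau] + 2 * x[tau:] + y[tau:]
    )
    counts = np.bincount(code, minlength=16).astype(float)
    return JointDistribution(probs=(counts / counts.sum()).reshape(2, 2, 2, 2))


def compute_mi(joint: JointDistribution, part: str = "pair") -> float:
    """Mutual information (bits) between a past grouping and the joint future.

    part = "pair" gives the TDMI I(X_t, Y_t; X_{t+tau}, Y_{t+tau});
    part = "x" gives i_x = I(X_t; X_{t+tau}, Y_{t+tau}); "y" likewise.
    """
    p = joint.probs
    if part == "pair":
        return _mi_bits(p.reshape(4, 4))
    if part == "x":
        return _mi_bits(p.sum(axis=1).reshape(2, 4))
    if part == "y":
        return _mi_bits(p.sum(axis=0).reshape(2, 4))
    raise ValueError(f"unknown part {part!r}; expected 'pair', 'x' or 'y'")


@dataclass(frozen=True)
class PidComponents:
    """MMI partial information decomposition of a pair's TDMI (bits)."""

    tdmi: float
    ri: float
    si: float
    ui_x: float
    ui_y: float
    i_x: float
    i_y: float

    def swapped(self) -> "PidComponents":
        """The decomposition with the roles of X and Y exchanged."""
        return PidComponents(
            tdmi=self.tdmi,
            ri=self.ri,
            si=self.si,
            ui_x=self.ui_y,
            ui_y=self.ui_x,
            i_x=self.i_y,
            i_y=self.i_x,
        )


def _clamp(value: float) -> float:
    if value < 0:
        if value < -_NEG_TOL:
            raise AssertionError(f"PID component unexpectedly negative: {value}")
        return 0.0
    return value


def pid_from_joint(joint: JointDistribution) -> PidComponents:
    """MMI decomposition computed directly from a 16-outcome distribution."""
    tdmi = compute_mi(joint, "pair")
    i_x = compute_mi(joint, "x")
    i_y = compute_mi(joint, "y")
    ri = min(i_x, i_y)
    return PidComponents(
        tdmi=_clamp(tdmi),
        ri=_clamp(ri),
        si=_clamp(tdmi - max(i_x, i_y)),
        ui_x=_clamp(i_x - ri),
        ui_y=_clamp(i_y - ri),
        i_x=_clamp(i_x),
        i_y=_clamp(i_y),
    )


def pid_decompose(
    x_series: np.ndarray, y_series: np.ndarray, tau: int = 1
) -> PidComponents:
    """Plug-in MMI decomposition of a binary pair's TDMI at delay ``tau``."""
    return pid_from_joint(estimate_joint(x_series, y_series, tau))


def all_pairs_pid(
    activity: np.ndarray,
    pop: NeuronPopulation,
    tau: int = 1,
    min_distance_um: Optional[float] = 100.0,
    pair_filter: Optional[Callable[[int, int, float], bool]] = None,
    max_pairs: Optional[int] = None,
    subsample_seed: int = 0,
) -> pd.DataFrame:
    """Per-pair PID table for a recording.

    One row per unordered pair (i < j, lexicographic) whose distance passes
    ``min_distance_um`` and the optional ``pair_filter(i, j, d)``. The
    (ui_x, ui_y) orientation follows the lower neuron id. ``max_pairs``
    optionally subsamples pairs uniformly (seeded) for quick runs.
    """
    activity = np.asarray(activity)
    if activity.ndim != 2:
        raise ValueError("activity must be a 2-D (time x neurons) array")
    if activity.shape[1] != pop.n_neurons:
        raise ValueError(
            f"activity has {activity.shape[1]} neurons, population has {pop.n_neurons}"
        )
    pairs = pop.pair_distances()
    if min_distance_um is not None:
        pairs = pairs[pairs["distance_um"] >= min_distance_um]
    if pair_filter is not None:
        keep = [
            pair_filter(int(r.i), int(r.j), float(r.distance_um))
            for r in pairs.itertuples()
        ]
        pairs = pairs[np.asarray(keep, dtype=bool)]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(subsample_seed)
        idx = np.sort(rng.choice(len(pairs), size=max_pairs, replace=False))
        pairs = pairs.iloc[idx]
    pairs = pairs.reset_index(drop=True)
    if pairs.empty:
        import warnings

        warnings.warn("no neuron pairs pass the distance filter", stacklevel=2)

    cols = {k: [] for k in ("tdmi", "ri", "si", "ui_x", "ui_y")}
    series = [activity[:, k].astype(np.int64) for k in range(pop.n_neurons)]
    for row in pairs.itertuples():
        pid = pid_decompose(series[int(row.i)], series[int(row.j)], tau)
        for k in cols:
            cols[k].append(getattr(pid, k))
    out = pairs.copy()
    for k, v in cols.items():
        out[k] = v
    return out
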