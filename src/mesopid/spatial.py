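"""Spatial decay profiles: distance binning, exponential fits, λ_eff.

Any per-pair quantity (Pearson correlation of the binary activity,
z-scored synergy or redundancy) is averaged inside logarithmically spaced
distance bins and the binned curve fitted with a three-parameter
exponential decay

    C(d) = C_inf + (C_0 - C_inf) * exp(-d / lambda)

where ``lambda`` (µm) is the correlation length, ``C_0`` the value at zero
separation and ``C_inf`` the large-distance baseline. When ``lambda``
exceeds the field of view the fitted value is poorly constrained; the
*effective information length*

    lambda_eff = (1 / C_0) * integral_{d0}^{dmax} C(d) dd

(with d0 = 100 µm, dmax = 1500 µm by default) is the robust spatial-extent
summary: a normalized area under the fitted curve with units of µm that
tends to dmax - d0 for a flat curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import curve_fit

from .exceptions import FitFailureError
from .population import NeuronPopulation

logger = logging.getLogger(__name__)

DEFAULT_D_MIN_UM = 100.0
DEFAULT_D_MAX_UM = 3000.0
DEFAULT_N_BINS = 20
DEFAULT_MIN_PAIRS = 50
LAMBDA_STARTS_UM = (100.0, 300.0, 1000.0, 3000.0)


def pairwise_pearson(
    activity: np.ndarray,
    pop: NeuronPopulation,
    min_distance_um: Optional[float] = None,
) -> pd.DataFrame:
    """Pearson correlation of every retained unordered neuron pair.

    Zero-variance neurons are excluded (their correlations are undefined)
    and logged; pairs closer than ``min_distance_um`` are dropped.
    """
    activity = np.asarray(activity, dtype=float)
    if activity.ndim != 2 or activity.shape[0] < 2 or activity.shape[1] < 2:
        raise ValueError("activity must be (time x neurons) with >=2 of each")
    if activity.shape[1] != pop.n_neurons:
        raise ValueError("activity and population neuron counts differ")
    variances = activity.var(axis=0)
    valid = variances > 0
    if not valid.any() or valid.sum() < 2:
        raise ValueError("fewer than two neurons with non-zero variance")
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("excluding %d zero-variance neurons from correlations", n_dropped)

    corr = np.corrcoef(activity[:, valid], rowvar=False)
    idx = np.flatnonzero(valid)
    pairs = pop.pair_distances()
    keep = valid[pairs["i"].to_numpy()] & valid[pairs["j"].to_numpy()]
    pairs = pairs[keep].reset_index(drop=True)
    remap = np.full(pop.n_neurons, -1)
    remap[idx] = np.arange(idx.size)
    pairs["value"] = corr[remap[pairs["i"]], remap[pairs["j"]]]
    if min_distance_um is not None:
        pairs = pairs[pairs["distance_um"] >= min_distance_um].reset_index(drop=True)
    return pairs


@dataclass(frozen=True)
class DistanceProfile:
    """A binned mean-vs-distance curve."""

    bin_edges_um: np.ndarray
    bin_centers_um: np.ndarray
    mean_value: np.ndarray
    sem: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_um": self.bin_centers_um,
                "mean": self.mean_value,
                "sem": self.sem,
                "n_pairs": self.n_pairs,
            }
        )


def log_spaced_edges(d_min_um: float, d_max_um: float, n_bins: int) -> np.ndarray:
    if d_min_um <= 0:
        raise ValueError("d_min_um must be positive for logarithmic bins")
    if d_max_um <= d_min_um:
        raise ValueError("d_max_um must exceed d_min_um")
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    return np.geomspace(d_min_um, d_max_um, n_bins + 1)


def bin_by_distance(
    values: pd.DataFrame,
    d_min_um: float = DEFAULT_D_MIN_UM,
    d_max_um: float = DEFAULT_D_MAX_UM,
    n_bins: int = DEFAULT_N_BINS,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    value_column: str = "value",
) -> DistanceProfile:
    """Average a per-pair quantity inside log-spaced distance bins.

    Bin centers are the geometric means of the edges; bins with fewer than
    ``min_pairs`` pairs are dropped (and logged).
    """
    if values.empty:
        raise ValueError("per-pair table is empty")
    edges = log_spaced_edges(d_min_um, d_max_um, n_bins)
    d = values["distance_um"].to_numpy(float)
    v = values[value_column].to_numpy(float)
    in_range = (d >= edges[0]) & (d <= edges[-1])
    d, v = d[in_range], v[in_range]
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)

    centers, means, sems, counts = [], [], [], []
    for b in range(n_bins):
        vals = v[which == b]
        if vals.size < min_pairs:
            if vals.size:
                logger.info("dropping bin %d with only %d pairs", b, vals.size)
            continue
        centers.append(float(np.sqrt(edges[b] * edges[b + 1])))
        means.append(float(vals.mean()))
        sems.append(float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0)
        counts.append(int(vals.size))
    return DistanceProfile(
        bin_edges_um=edges,
        bin_centers_um=np.array(centers),
        mean_value=np.array(means),
        sem=np.array(sems),
        n_pairs=np.array(counts),
    )


def decay_model(d: np.ndarray, c0: float, c_inf: float, lambda_um: float) -> np.ndarray:
    """Exponential decay C(d) = C_inf + (C_0 - C_inf) exp(-d / lambda)."""
    return c_inf + (c0 - c_inf) * np.exp(-np.asarray(d, float) / lambda_um)


@dataclass(frozen=True)
class DecayFit:
    """Fitted exponential-decay parameters and diagnostics."""

    c0: float
    c_inf: float
    lambda_um: float
    covariance: np.ndarray
    fit_ok: bool
    residuals: np.ndarray
    flags: tuple = ()

    def predict(self, d: np.ndarray) -> np.ndarray:
        return decay_model(d, self.c0, self.c_inf, self.lambda_um)


def fit_exponential_decay(
    profile: DistanceProfile,
    weighted: bool = False,
    lambda_starts_um: tuple = LAMBDA_STARTS_UM,
) -> DecayFit:
    """Nonlinear least squares of the decay model on a binned profile.

    Multi-start over a fixed grid of initial decay lengths; the best start
    by residual sum of squares wins, keeping the result deterministic.
    ``weighted=True`` weights residuals by 1/SEM.
    """
    d = profile.bin_centers_um
    y = profile.mean_value
    if d.size < 4:
        raise ValueError("need at least 4 retained bins to fit 3 parameters")
    if np.ptp(y) < 1e-12:
        return DecayFit(
            c0=float(y[0]),
            c_inf=float(y[-1]),
            lambda_um=np.nan,
            covariance=np.full((3, 3), np.nan),
            fit_ok=False,
            residuals=np.zeros_like(y),
            flags=("unidentifiable_lambda",),
        )
    sigma = None
    if weighted:
        sigma = np.where(profile.sem > 0, profile.sem, profile.sem[profile.sem > 0].min())

    best = None
    for lam0 in lambda_starts_um:
        try:
            popt, pcov = curve_fit(
                decay_model,
                d,
                y,
                p0=[float(y[0]), float(y[-1]), lam0],
                sigma=sigma,
                bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - decay_model(d, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise FitFailureError("exponential decay fit failed from every start")
    _, popt, pcov = best
    residuals = y - decay_model(d, *popt)
    return DecayFit(
        c0=float(popt[0]),
        c_inf=float(popt[1]),
        lambda_um=float(popt[2]),
        covariance=pcov,
        fit_ok=True,
        residuals=residuals,
    )


def normalize_profile(profile: DistanceProfile, fit: DecayFit) -> DistanceProfile:
    """Rescale a profile to (C(d) - C_inf) / (C_0 - C_inf), so the fitted
    curve becomes exp(-d / lambda): 1 at d = 0 and 1/e at d = lambda."""
    if not fit.fit_ok:
        raise ValueError("cannot normalize with a failed fit")
    span = fit.c0 - fit.c_inf
    if abs(span) < 1e-12:
        raise ZeroDivisionError("degenerate normalization: C_0 == C_inf")
    return replace(
        profile,
        mean_value=(profile.mean_value - fit.c_inf) / span,
        sem=profile.sem / abs(span),
    )


@dataclass(frozen=True)
class EffectiveLength:
    """Normalized area under a fitted decay curve (µm)."""

    lambda_eff_um: float
    d0_um: float
    dmax_um: float


def lambda_eff_closed_form(
    c0: float, c_inf: float, lambda_um: float, d0_um: float, dmax_um: float
) -> float:
    """Antiderivative form of the normalized area under the decay curve."""
    if c0 == 0:
        raise ZeroDivisionError("lambda_eff undefined for C_0 = 0")
    area = c_inf * (dmax_um - d0_um) + (c0 - c_inf) * lambda_um * (
        np.exp(-d0_um / lambda_um) - np.exp(-dmax_um / lambda_um)
    )
    return float(area / c0)


def effective_information_length(
    fit: DecayFit, d0_um: float = 100.0, dmax_um: float = 1500.0
) -> EffectiveLength:
    """λ_eff by numerical quadrature of the fitted curve over [d0, dmax]."""
    if not fit.fit_ok:
        raise ValueError("cannot integrate a failed fit")
    if fit.c0 == 0:
        raise ZeroDivisionError("lambda_eff undefined for C_0 = 0")
    if d0_um >= dmax_um:
        raise ValueError("d0_um must be smaller than dmax_um")
    area, _ = quad(fit.predict, d0_um, dmax_um, limit=200)
    return EffectiveLength(
        lambda_eff_um=float(area / fit.c0), d0_um=d0_um, dmax_um=dmax_um
    )
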