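"""Two-state HMM binarization of deconvolved activity traces.

Each neuron's continuous trace is modelled as a hidden Markov chain with
two Gaussian-emission states — Quiet (0) and Active (1, the higher
emission mean). Per-frame states are assigned by the posterior marginal
maximum (forward-backward), avoiding any hand-set amplitude threshold;
Viterbi decoding is available as an option. Fitting uses
expectation-maximization with deterministic quantile-based initializations
and a best-of-``n_restarts`` selection by log-likelihood.

Constant (zero-variance) traces carry no state information; they raise
:class:`~mesopid.exceptions.DegenerateTraceError`, which the dataset-level
entry point maps to an all-Quiet neuron and records in the fit report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .exceptions import DegenerateTraceError

# (low, high) trace quantiles seeding the emission means of each restart;
# sparse activity puts the Active level in the upper tail, so the restarts
# probe increasingly extreme splits.
_RESTART_QUANTILES = ((25.0, 75.0), (10.0, 90.0), (50.0, 99.0), (5.0, 99.9))


@dataclass(frozen=True)
class HmmModel:
    """A fitted two-state model with Active relabeled to the higher mean."""

    transition_matrix: np.ndarray
    emission_means: np.ndarray
    emission_sds: np.ndarray
    initial_probs: np.ndarray
    log_likelihood: float
    converged: bool

    def __post_init__(self) -> None:
        t = np.asarray(self.transition_matrix, float)
        if t.shape != (2, 2) or np.abs(t.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("transition_matrix must be 2x2 row-stochastic")
        if np.any(np.asarray(self.emission_sds) <= 0):
            raise ValueError("emission_sds must be positive")
        if self.emission_means[1] < self.emission_means[0]:
            raise ValueError("state 1 (Active) must have the larger mean")

    def _to_hmmlearn(self) -> GaussianHMM:
        model = GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        model.startprob_ = np.asarray(self.initial_probs, float)
        model.transmat_ = np.asarray(self.transition_matrix, float)
        model.means_ = np.asarray(self.emission_means, float).reshape(2, 1)
        model.covars_ = np.asarray(self.emission_sds, float).reshape(2, 1) ** 2
        return model


def _relabel(model: GaussianHMM) -> GaussianHMM:
    """Ensure state 1 is the higher-mean (Active) state."""
    if model.means_[1, 0] >= model.means_[0, 0]:
        return model
    order = [1, 0]
    model.startprob_ = model.startprob_[order]
    model.transmat_ = model.transmat_[np.ix_(order, order)]
    model.means_ = model.means_[order]
    model.covars_ = model._covars_[order]
    return model


def fit_two_state_hmm(
    trace: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-4,
    n_restarts: int = 3,
    seed: int = 0,
) -> HmmModel:
    """Fit a Gaussian two-state HMM by EM, best of ``n_restarts``."""
    trace = np.asarray(trace, dtype=float).ravel()
    if trace.size < 50:
        raise ValueError("trace must contain at least 50 frames")
    if not np.isfinite(trace).all():
        raise ValueError("trace contains non-finite values")
    if trace.var() == 0:
        raise DegenerateTraceError("trace has zero variance")
    obs = trace.reshape(-1, 1)
    sd0 = max(trace.std(), 1e-6)

    best: Optional[GaussianHMM] = None
    best_score = -np.inf
    for r in range(max(1, n_restarts)):
        q_lo, q_hi = _RESTART_QUANTILES[r % len(_RESTART_QUANTILES)]
        means0 = np.percentile(trace, [q_lo, q_hi])
        if means0[0] == means0[1]:
            means0 = np.array([trace.min(), trace.max()])
        model = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            n_iter=max_iter,
            tol=tol,
            init_params="",
            params="stmc",
            random_state=seed + r,
            min_covar=1e-10,
        )
        model.startprob_ = np.array([0.5, 0.5])
        model.transmat_ = np.array([[0.9, 0.1], [0.1, 0.9]])
        model.means_ = means0.reshape(2, 1)
        model.covars_ = np.full((2, 1), sd0**2)
        try:
            model.fit(obs)
            score = model.score(obs)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if score > best_score:
            best, best_score = model, score
    if best is None:
        raise DegenerateTraceError("EM failed from every restart")
    best = _relabel(best)
    return HmmModel(
        transition_matrix=best.transmat_.copy(),
        emission_means=best.means_.ravel().copy(),
        emission_sds=np.sqrt(best._covars_.ravel().copy()),
        initial_probs=best.startprob_.copy(),
        log_likelihood=float(best_score),
        converged=bool(best.monitor_.converged),
    )


def decode_states(
    model: HmmModel, trace: np.ndarray, method: str = "posterior"
) -> np.ndarray:
    """Binary state sequence for a trace under a fitted model.

    ``method='posterior'`` takes the per-frame forward-backward marginal
    maximum (the default); ``'viterbi'`` returns the jointly most probable
    path.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if trace.size == 0:
        raise ValueError("trace is empty")
    hm = model._to_hmmlearn()
    obs = trace.reshape(-1, 1)
    if method == "posterior":
        posterior = hm.predict_proba(obs)
        return posterior.argmax(axis=1).astype(np.int8)
    if method == "viterbi":
        return hm.predict(obs).astype(np.int8)
    raise ValueError(f"unknown decoding method {method!r}")


def binarize_dataset(
    traces: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-4,
    n_restarts: int = 3,
    seed: int = 0,
    method: str = "posterior",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Fit-and-decode every neuron of a (time x neurons) trace matrix.

    Returns the binary activity matrix and a per-neuron fit report.
    Degenerate (constant) traces become all-Quiet and are flagged.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.size == 0:
        raise ValueError("traces must be a non-empty (time x neurons) matrix")
    n_frames, n_neurons = traces.shape
    activity = np.zeros((n_frames, n_neurons), dtype=np.int8)
    report = []
    for k in range(n_neurons):
        try:
            model = fit_two_state_hmm(
                traces[:, k], max_iter=max_iter, tol=tol,
                n_restarts=n_restarts, seed=seed + 1000 * k,
            )
        except DegenerateTraceError:
            report.append(
                {"neuron_id": k, "status": "degenerate", "converged": False,
                 "mean_quiet": np.nan, "mean_active": np.nan,
                 "sd_quiet": np.nan, "sd_active": np.nan,
                 "log_likelihood": np.nan}
            )
            continue
        activity[:, k] = decode_states(model, traces[:, k], method=method)
        report.append(
            {"neuron_id": k, "status": "ok", "converged": model.converged,
             "mean_quiet": model.emission_means[0],
             "mean_active": model.emission_means[1],
             "sd_quiet": model.emission_sds[0],
             "sd_active": model.emission_sds[1],
             "log_likelihood": model.log_likelihood}
        )
    return activity, pd.DataFrame(report)
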