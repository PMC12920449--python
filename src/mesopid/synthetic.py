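"""Synthetic mesoscale recordings with known spatial and temporal structure.

The generator emulates the statistics the downstream analysis targets:

* a population of neurons scattered uniformly over a millimetre-scale field
  of view;
* sparse binary activity from a *dichotomized Gaussian*: a latent Gaussian
  field whose spatial correlation decays exponentially with distance
  (known decay length ``lambda_true_um``) and which evolves in time as an
  AR(1) process, thresholded so each neuron is Active on a target fraction
  of frames;
* canonical two-neuron motifs (XOR, copy, independent, noisy copy) whose
  information decomposition is known in closed form;
* calcium-like continuous traces (state amplitude plus Gaussian noise) for
  exercising the HMM binarization stage.

The latent correlation — not the binary correlation — follows the
exponential form; in the sparse, small-correlation regime the thresholded
binary correlations inherit the decay length to good approximation, which
is what the recovery tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple, Union

import numpy as np
from scipy import signal
from scipy.stats import norm

from .exceptions import GenerationError
from .population import NeuronPopulation

MOTIF_KINDS = ("xor", "copy", "independent", "noisy_copy")


@dataclass(frozen=True)
class ActivityParams:
    """Parameters of the dichotomized-Gaussian activity generator.

    lambda_true_um
        spatial decay length of the latent correlation (µm).
    c0_latent, c_inf_latent
        latent correlation at zero separation (excluding the unit diagonal)
        and at infinite separation; ``c_inf_latent <= c0_latent < 1``.
    rate
        target per-frame activation probability.
    ar_coeff
        temporal AR(1) coefficient of the latent field, in [0, 1).
    """

    lambda_true_um: float = 400.0
    c0_latent: float = 0.3
    c_inf_latent: float = 0.02
    rate: float = 0.05
    ar_coeff: float = 0.5
    n_frames: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.c_inf_latent <= self.c0_latent < 1.0):
            raise ValueError("require c_inf_latent <= c0_latent < 1")
        if not (0.0 < self.rate < 1.0):
            raise ValueError("rate must lie in (0, 1)")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.lambda_true_um <= 0:
            raise ValueError("lambda_true_um must be positive")
        if self.n_frames < 100:
            raise ValueError("n_frames must be at least 100")


@dataclass(frozen=True)
class MotifPair:
    """A two-neuron binary motif with its generating parameters."""

    motif_kind: str
    x_series: np.ndarray
    y_series: np.ndarray
    generating_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.x_series, dtype=np.int8)
        y = np.asarray(self.y_series, dtype=np.int8)
        object.__setattr__(self, "x_series", x)
        object.__setattr__(self, "y_series", y)
        if x.shape != y.shape or x.ndim != 1 or x.size < 2:
            raise ValueError("series must be equal-length 1-D with length >= 2")
        for s in (x, y):
            if not np.isin(s, (0, 1)).all():
                raise ValueError("series must be binary")


def generate_population(
    n_neurons: int, field_width_um: float, field_height_um: float, seed: int
) -> NeuronPopulation:
    """Scatter ``n_neurons`` uniformly at random over the field of view."""
    if n_neurons < 2:
        raise ValueError("n_neurons must be at least 2")
    if field_width_um <= 0 or field_height_um <= 0:
        raise ValueError("field dimensions must be positive")
    rng = np.random.default_rng(seed)
    return NeuronPopulation(
        x_um=rng.uniform(0.0, field_width_um, n_neurons),
        y_um=rng.uniform(0.0, field_height_um, n_neurons),
        field_width_um=field_width_um,
        field_height_um=field_height_um,
    )


def latent_covariance(pop: NeuronPopulation, params: ActivityParams) -> np.ndarray:
    """Exponential-decay latent correlation matrix (unit diagonal)."""
    d = pop.distance_matrix()
    sigma = params.c_inf_latent + (params.c0_latent - params.c_inf_latent) * np.exp(
        -d / params.lambda_true_um
    )
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _repair_covariance(sigma: np.ndarray) -> np.ndarray:
    """Clip tiny negative eigenvalues and restore the unit diagonal.

    Fails only if the spectrum is substantially negative (min eig < -1e-6),
    which would mean the requested correlation structure is not a valid
    correlation matrix rather than a rounding artifact.
    """
    eigval, eigvec = np.linalg.eigh(sigma)
    if eigval.min() < -1e-6:
        raise GenerationError(
            f"latent covariance is not repairable: min eigenvalue {eigval.min():.3e}"
        )
    if eigval.min() >= 1e-10:
        return sigma
    eigval = np.clip(eigval, 1e-10, None)
    repaired = (eigvec * eigval) @ eigvec.T
    scale = np.sqrt(np.diag(repaired))
    repaired /= np.outer(scale, scale)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def generate_correlated_activity(
    pop: NeuronPopulation, params: ActivityParams
) -> np.ndarray:
    """Binary activity (n_frames × n_neurons) from a dichotomized Gaussian.

    The latent field has unit-variance marginals, spatial correlation
    ``c_inf + (c0 - c_inf) * exp(-d/lambda)`` and AR(1) temporal dynamics
    ``z_t = a z_{t-1} + sqrt(1 - a^2) eps_t`` with correlated innovations,
    so the stationary spatial covariance equals the target. A neuron is
    Active whenever its latent value exceeds the (1 - rate) normal quantile.
    """
    rng = np.random.default_rng(params.seed)
    sigma = _repair_covariance(latent_covariance(pop, params))
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(pop.n_neurons))

    eps = rng.standard_normal((params.n_frames, pop.n_neurons))
    innovations = eps @ chol.T
    a = params.ar_coeff
    innovations[1:] *= np.sqrt(1.0 - a * a)
    # z_t = a z_{t-1} + e_t, with e_0 drawn at the stationary scale
    latent = signal.lfilter([1.0], [1.0, -a], innovations, axis=0)
    threshold = norm.ppf(1.0 - params.rate)
    return (latent > threshold).astype(np.int8)


def _flip(bits: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    return np.where(rng.random(bits.shape) < p, 1 - bits, bits).astype(np.int8)


def _noise_pair(noise: Union[float, Tuple[float, float]]) -> Tuple[float, float]:
    if np.isscalar(noise):
        return float(noise), float(noise)
    nx, ny = noise
    return float(nx), float(ny)


def generate_motif_pair(
    motif_kind: str,
    n_frames: int,
    noise: Union[float, Tuple[float, float]] = 0.1,
    p_marginal: float = 0.5,
    seed: int = 0,
) -> MotifPair:
    """Simulate one of the canonical two-neuron motifs.

    xor
        each frame draws fresh fair bits (X_t, Y_t); the next X is their
        XOR while the next Y is a fresh fair bit — a purely synergistic
        relation between the pair's past and its joint future.
    copy
        Y mirrors X exactly; X is a symmetric flip chain with flip
        probability ``noise`` — purely redundant.
    independent
        two independent flip chains (per-series rates allowed as a tuple),
        started at Bernoulli(``p_marginal``).
    noisy_copy
        the copy motif with independent bit-flip noise on Y's read-out.
    """
    if motif_kind not in MOTIF_KINDS:
        raise ValueError(f"unknown motif_kind {motif_kind!r}; expected one of {MOTIF_KINDS}")
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    rng = np.random.default_rng(seed)
    nx, ny = _noise_pair(noise)

    if motif_kind == "xor":
        # Y is a fresh fair bit each frame; X_{t+1} = X_t XOR Y_t. Since
        # Y_t is fair and independent of X_t, X stays marginally fair and
        # independent of the concurrent Y — the pair's past determines the
        # next X while carrying no single-series information about it.
        y = rng.integers(0, 2, n_frames).astype(np.int8)
        x0 = np.int8(rng.integers(0, 2))
        # X_{t+1} = x0 XOR y_0 XOR ... XOR y_t  (cumulative XOR, vectorized)
        x = np.concatenate([[x0], (x0 + np.cumsum(y[:-1])) % 2]).astype(np.int8)
    elif motif_kind == "copy":
        x = _flip_chain(n_frames, nx, 0.5, rng)
        y = x.copy()
    elif motif_kind == "independent":
        x = _flip_chain(n_frames, nx, p_marginal, rng)
        y = _flip_chain(n_frames, ny, p_marginal, rng)
    else:  # noisy_copy
        x = _flip_chain(n_frames, nx, 0.5, rng)
        y = _flip(x, ny, rng)

    return MotifPair(
        motif_kind=motif_kind,
        x_series=x,
        y_series=y,
        generating_params={
            "noise": (nx, ny),
            "p_marginal": p_marginal,
            "n_frames": n_frames,
            "seed": seed,
        },
    )


def _flip_chain(
    n_frames: int, flip_p: float, p_init: float, rng: np.random.Generator
) -> np.ndarray:
    """Binary Markov chain: state flips each step with probability flip_p."""
    flips = (rng.random(n_frames - 1) < flip_p).astype(np.int8)
    x0 = np.int8(rng.random() < p_init)
    # cumulative XOR of flips gives the chain without a Python loop
    states = np.concatenate([[x0], (x0 + np.cumsum(flips)) % 2]).astype(np.int8)
    return states


def analytic_motif_joint(
    motif_kind: str,
    noise: Union[float, Tuple[float, float]] = 0.1,
    p_marginal: float = 0.5,
) -> np.ndarray:
    """Exact stationary joint of (X_t, Y_t, X_{t+1}, Y_{t+1}) for a motif.

    Returns a (2, 2, 2, 2) probability array indexed [x, y, x1, y1].
    Flip chains are taken at their stationary marginal (1/2); the
    ``p_marginal`` of the independent motif only sets the initial state of
    simulated realizations and drops out at stationarity.
    """
    if motif_kind not in MOTIF_KINDS:
        raise ValueError(f"unknown motif_kind {motif_kind!r}")
    nx, ny = _noise_pair(noise)
    p = np.zeros((2, 2, 2, 2))

    def flip_kernel(eta: float) -> np.ndarray:
        return np.array([[1 - eta, eta], [eta, 1 - eta]])

    if motif_kind == "xor":
        for x in (0, 1):
            for y in (0, 1):
                for y1 in (0, 1):
                    p[x, y, x ^ y, y1] = 0.25 * 0.5
    elif motif_kind == "copy":
        k = flip_kernel(nx)
        for x in (0, 1):
            for x1 in (0, 1):
                p[x, x, x1, x1] = 0.5 * k[x, x1]
    elif motif_kind == "independent":
        kx, ky = flip_kernel(nx), flip_kernel(ny)
        for x in (0, 1):
            for y in (0, 1):
                for x1 in (0, 1):
                    for y1 in (0, 1):
                        p[x, y, x1, y1] = 0.25 * kx[x, x1] * ky[y, y1]
    else:  # noisy_copy: latent chain L, X = L, Y = L with read-out noise
        k = flip_kernel(nx)
        obs = flip_kernel(ny)
        for l0 in (0, 1):
            for l1 in (0, 1):
                w = 0.5 * k[l0, l1]
                for y in (0, 1):
                    for y1 in (0, 1):
                        p[l0, y, l1, y1] += w * obs[l0, y] * obs[l1, y1]
    assert abs(p.sum() - 1.0) < 1e-12
    return p


def generate_calcium_like_traces(
    activity: np.ndarray, amp_active: float, noise_sd: float, seed: int = 0
) -> np.ndarray:
    """Continuous traces: ``amp_active * state + N(0, noise_sd)`` per frame."""
    activity = np.asarray(activity)
    if not np.isin(activity, (0, 1)).all():
        raise ValueError("activity must be binary")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if amp_active <= 0:
        raise ValueError("amp_active must be positive")
    rng = np.random.default_rng(seed)
    return amp_active * activity.astype(float) + rng.normal(
        0.0, noise_sd, activity.shape
    )
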