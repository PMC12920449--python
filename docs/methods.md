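# Methods

This note documents the models and procedures implemented in `mesopid`,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic-data tests do and do not establish about real recordings.

## Binarization (two-state HMM)

Each neuron's continuous trace is modelled as a two-state hidden Markov
chain with Gaussian emissions; state 1 ("Active") is relabelled to the
higher emission mean after fitting. Decoding is per-frame posterior
marginal maximum (forward-backward), i.e. the most probable state at each
time point; Viterbi is available as an option but answers a different
question (the most probable *path*). Fitting uses EM (hmmlearn) with
deterministic initializations from trace quantiles — restarts probe
increasingly extreme low/high quantile splits, which matters for sparse
activity where the Active level sits in the upper tail — and the best of
`n_restarts=3` restarts by log-likelihood is kept. Defaults:
`max_iter=200`, `tol=1e-4` (log-likelihood change). Gaussian emissions are
a modelling choice for deconvolved-rate traces; a count-based emission
family would be an alternative the package does not implement. Constant
traces are degenerate (no state information) and are mapped to all-Quiet
with a flag in the per-neuron fit report rather than fitted.

## Information decomposition

All information quantities are in bits (base-2 logarithms). For a pair of
binary series at delay τ (frames; default 1), the 16-outcome joint of
(X_t, Y_t, X_{t+τ}, Y_{t+τ}) is estimated by plug-in (maximum-likelihood)
frequencies with no pseudocounts. The decomposition uses the
minimum-mutual-information redundancy:

* RI = min(i_X, i_Y), where i_X = I(X_t; X_{t+τ}, Y_{t+τ});
* UI_X = i_X − RI and UI_Y = i_Y − RI (one of the two is identically 0);
* SI = TDMI − max(i_X, i_Y), non-negative because joint information is
  never below single-source information.

Tiny negative float residues (> −1e−9) are clamped to zero; anything more
negative raises, as it would indicate a bug rather than round-off. The
plug-in estimator is deliberately uncorrected: its finite-sample bias is
handled by the null-model normalization, which measures its nulls with
the same estimator at the same length.

Pair tables enumerate unordered pairs (i < j, lexicographic), record the
(UI_X, UI_Y) orientation against the lower neuron id, and by default drop
pairs closer than 100 µm — the same bound as the effective-length
integral, avoiding the short-range regime where the exponential model is
known to fit poorly.

## Null-model z-scoring

A null system is a Markov chain on the four joint states of a binary pair
whose transition distribution p(x′, y′ | x, y) has each row drawn from a
flat Dirichlet over the four outcomes, followed by independent bit-flip
noise at rate η on both future bits. The stationary TDMI of the noisy
chain decreases from its noiseless value to 0 at η = 1/2, so η is tuned
by bisection (depth 60) until the *analytic* stationary TDMI matches the
empirical pair's TDMI within `tolerance = max(1e−3 bits, 1% of target)`.
Systems whose noiseless TDMI falls short of the target are redrawn, up to
`max_retries=50`. The stationary distribution is obtained by power
iteration accelerated through repeated squaring of the transition matrix
(tolerance 1e−12), which converges in a handful of 4×4 multiplications.

Each accepted null is simulated for the same number of frames as the
empirical pair (a numba-compiled kernel makes this cheap) and its PID is
computed with the same plug-in estimator; z-scores use the ensemble mean
and sample SD (`n_null=100` by default). Rows whose TDMI is unattainable
within the retry budget, or whose ensemble has zero spread in a
component, are flagged — never silently dropped.

Two properties of this family are worth knowing:

* Its attainable TDMI range is bounded: flat-Dirichlet transitions carry
  ~0.3 bits on average and essentially never exceed ~0.8 bits. Empirical
  neural pairs (TDMI ~10⁻³–10⁻¹ bits) are far inside the range;
  deterministic toy motifs such as a noiseless XOR (1 bit) are outside it
  and correctly raise the unattainable-TDMI error.
* The bisection target is the empirical *plug-in* TDMI, which carries an
  upward bias of roughly (K−1)/(2T ln 2) bits (K = 16 cells). At the
  recording lengths the package targets (~20,000 frames) this residual
  mismatch is negligible; at very short lengths (~2,000 frames) it shifts
  the self-calibration z means of RI/SI to ≈ −0.2. Calibration checks are
  therefore run length-matched to the emulated recordings, and
  calibration self-draws are rejected above 0.35 bits so their targets
  remain matchable by fresh ensembles.

## Spatial profiles and decay fits

Per-pair quantities are averaged in log-spaced distance bins (default 20
bins over [100, 3000] µm, geometric-mean bin centers, bins with fewer
than 50 pairs dropped). The binned curve is fitted with
C(d) = C_∞ + (C_0 − C_∞) e^{−d/λ} by unweighted nonlinear least squares
(SEM-weighted option available; the unweighted fit is the default because
bin SEMs at short distances are driven by pair counts, not measurement
quality). Initialization is multi-start over a fixed decay-length grid
{100, 300, 1000, 3000} µm with C_0/C_∞ seeded from the first/last bins;
the best start by residual sum of squares wins, keeping fits
deterministic. λ is bounded positive; C_0 and C_∞ are unbounded.
Near-constant profiles (peak-to-peak < 1e−12) are flagged
`unidentifiable_lambda` instead of fitted. Note that C_0 is the model
value at d = 0, an extrapolation below the first bin center; on null data
the fit may park a tiny λ with a large C_0 while remaining flat
everywhere in the fitted range — consumers should read λ together with
the curve, which is why the pipeline reports λ_eff as the primary
spatial-extent summary for slowly decaying quantities.

The effective information length λ_eff = (1/C_0)·∫_{d0}^{dmax} C(d) dd
(defaults d0 = 100 µm, dmax = 1500 µm) is computed by adaptive quadrature
and agrees with the antiderivative to 1e−9 relative; for a flat curve it
equals dmax − d0 = 1400 µm, its upper limit. The integral uses the full
fitted curve including the C_∞ baseline (a baseline-subtracted variant is
a one-line change via the normalized profile).

## Multiplex networks and path decomposition

Layers are built per component (z_SI for synergy, z_RI for redundancy;
raw-bits weights optional): each node keeps its k strongest edges
(default k = 10 — a free parameter of the analysis; results should be
read per k), descending weight with ties broken toward the lower neighbor
id, and an edge survives if either endpoint selects it. The combined
network is the union of the two edge sets. All-pairs hop distances (BFS,
networkx) in layer A, layer B and the union classify each pair:
complementary (d_U < min(d_A, d_B)), shared (d_U = d_A = d_B — equivalent
to d_U = max given d_U ≤ min), or unique to the faster layer. Pairs
disconnected even in the union are reported separately and excluded from
proportions. Per-length proportions use the union-network path length as
the axis, with a pooled row for long paths (d_U ≥ 4). Across datasets the
per-length curves are summarized by the median and a 2.5–97.5 percentile
band.

## Group statistics

Condition contrasts are oriented stimulated minus spontaneous, with a
two-sided permutation test on the difference of group means: exhaustive
enumeration when the number of relabelings is ≤ 100,000 (exact fraction),
otherwise Monte Carlo with `n_perm=10,000` draws and add-one smoothing so
p > 0. With n = 3 per group the exhaustive floor is p = 2/20 = 0.1; small
synthetic studies cannot reach smaller p-values regardless of effect
size. Hedges' g applies the small-sample correction
J = 1 − 3/(4(n_a + n_b) − 9) to Cohen's d with the pooled SD.

## Synthetic data: what it does and does not emulate

The generator dichotomizes a latent Gaussian field: spatial correlation
Σ_ij = c_inf + (c0 − c_inf)·e^{−d_ij/λ} (unit diagonal), AR(1) temporal
dynamics z_t = a·z_{t−1} + √(1−a²)·ε_t with correlated innovations (so
the stationary spatial covariance equals the target), and thresholding at
the (1 − rate) normal quantile. Defaults: rate 0.05 per frame, a = 0.5,
c0 = 0.3, c_inf = 0.02, 20,000 frames (~45 min at 7.5 Hz), fields of
3 × 3 mm with uniformly scattered neurons; conditions differ only in λ
(400 µm spontaneous vs 900 µm stimulated), mirroring the observation that
stimulation lengthens the decay without changing the short-range
amplitude. Covariance repair clips eigenvalues below 1e−10 and restores
the unit diagonal, failing only if the minimum eigenvalue is < −1e−6.

The *latent* correlation follows the exponential form; the binary
correlations inherit the decay length only approximately. Thresholding
compresses large short-range correlations more than small distant ones,
so fitted λ systematically underestimates the latent λ by ~15–20% at the
default amplitudes. Recovery tests therefore check relative error and
cross-condition ordering, not exact equality — and passing them shows the
estimator tracks a known monotone transform of ground truth, not that
real calcium data obey a dichotomized Gaussian. The generator has a
single global firing rate, no cell-to-cell rate heterogeneity, no
calcium-kernel temporal structure, no avalanche statistics, and its
motifs are stationary; conclusions about those aspects of real data are
outside what the test suite establishes.

Calcium-like traces are amplitude-times-state plus white Gaussian noise —
sufficient to exercise the HMM stage at controlled SNR, not a
biophysical forward model.

## Problem sizes and determinism

Test and demonstration runs use desk-scale sizes chosen to exercise every
code path with stable statistics: condition studies at 200 neurons ×
10,000 frames × 3 datasets per condition; null-model calibration at 200
pairs × 100 nulls × 20,000 frames; multiplex demos at 120 neurons with a
1,000-pair subsample and 30 nulls. The pipeline derives every stage seed
by stable hashing of (global seed, stage, dataset), so identical configs
reproduce identical reports; the all-pairs PID cost is O(n²T) and a
seeded pair-subsample option keeps exploratory runs cheap.
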