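# mesopid

Spatial structure of pairwise correlations and of synergistic/redundant
information interactions in large neural population recordings.

Mesoscale two-photon calcium imaging records thousands of cortical neurons
across several millimetres at once. At that scale two related questions
arise: how far do pairwise correlations extend in space (the *correlation
length*, a signature of dynamics near criticality), and what *kind* of
statistical interaction carries them — information that both neurons share
redundantly, or information that only emerges from the pair jointly
(synergy)? `mesopid` implements the full analysis chain for these
questions, exercised end to end on synthetic recordings with known ground
truth, so every stage is testable without any imaging data.

## What the package computes

**Binarization.** Each neuron's deconvolved activity trace is reduced to
Active/Quiet states with a per-neuron two-state Gaussian HMM
(posterior-marginal decoding; no hand-set amplitude threshold).

**Time-delayed mutual information and its decomposition.** For a pair of
binary neurons X, Y, the time-delayed mutual information at delay τ (in
frames, default 1),

    TDMI = I(X_t, Y_t ; X_{t+τ}, Y_{t+τ}),

is decomposed into redundant (RI), synergistic (SI) and unique
(UI_X, UI_Y) components with the minimum-mutual-information redundancy:
RI = min(i_X, i_Y) with i_X = I(X_t; X_{t+τ}, Y_{t+τ}),
UI_X = i_X − RI, UI_Y = i_Y − RI, SI = TDMI − max(i_X, i_Y).
All components are non-negative, they sum to the TDMI, and one unique term
is always zero. Estimation is plug-in on the 16-cell empirical joint, in
bits.

**Null-model z-scoring.** Raw components are biased by recording length
and firing rates, so each pair is z-scored against an ensemble of random
two-neuron Markov systems (Dirichlet-random transition structure plus
bit-flip noise) tuned by bisection to carry the *same TDMI* as the pair
and simulated at the same length — the ensemble shares the estimator's
finite-sample bias.

**Spatial profiles.** Any per-pair quantity (Pearson correlation of the
binary states, z-scored synergy or redundancy) is averaged in log-spaced
distance bins and fitted with

    C(d) = C_∞ + (C_0 − C_∞) e^{−d/λ},

giving the correlation length λ (µm). When λ exceeds the field of view,
the *effective information length*
λ_eff = (1/C_0) ∫_{d0}^{dmax} C(d) dd  (d0 = 100 µm, dmax = 1500 µm)
is the robust spatial-extent summary.

**Multiplex path decomposition.** The z-scored synergy and redundancy
weights define two interaction layers, each sparsified to an unweighted
kNN graph. Comparing shortest-path hop counts in each layer with those in
the union network classifies every node pair as *complementary* (the
mixed-layer route is strictly shorter), *shared*, or *unique* to one
layer, summarized per path length with special attention to long paths
(length ≥ 4).

**Condition statistics.** Per-dataset summaries (λ, λ_eff, long-path
proportions) are contrasted between spontaneous and stimulated conditions
with two-sample permutation tests on the mean difference and Hedges' g.

**Synthetic data.** A dichotomized-Gaussian generator produces sparse
binary activity whose latent spatial correlation decays exponentially with
a known length (default 400 µm "spontaneous", 900 µm "stimulated"), with
AR(1) temporal dynamics, plus canonical two-neuron motifs (XOR, copy,
independent, noisy copy) with closed-form decompositions and calcium-like
traces for the HMM stage.

## Worked example

```python
import mesopid as m

pop = m.generate_population(n_neurons=200, field_width_um=3000,
                            field_height_um=3000, seed=0)
params = m.ActivityParams(lambda_true_um=900.0, rate=0.05,
                          n_frames=10_000, seed=1)
activity = m.generate_correlated_activity(pop, params)

pairs = m.pairwise_pearson(activity, pop, min_distance_um=100.0)
profile = m.bin_by_distance(pairs)
fit = m.fit_exponential_decay(profile)
eff = m.effective_information_length(fit)
print(f"C0 = {fit.c0:.4f}, C_inf = {fit.c_inf:.4f}")
print(f"lambda = {fit.lambda_um:.1f} um, lambda_eff = {eff.lambda_eff_um:.1f} um")

pid = m.pid_decompose(activity[:, 0], activity[:, 1], tau=1)
print(f"TDMI = {pid.tdmi:.5f} bits (RI={pid.ri:.5f}, SI={pid.si:.5f}, "
      f"UIx={pid.ui_x:.5f}, UIy={pid.ui_y:.5f})")

from mesopid import numit
z = numit.numit_normalize(pid, series_length=9999, n_null=100, seed=2)
print(f"z_RI = {z.z_ri:+.2f}, z_SI = {z.z_si:+.2f}")
```

prints

```
C0 = 0.0929, C_inf = 0.0052
lambda = 767.3 um, lambda_eff = 611.3 um
TDMI = 0.02893 bits (RI=0.01403, SI=0.01400, UIx=0.00000, UIy=0.00090)
z_RI = +2.52, z_SI = -0.34
```

The 10,000-frame recording of 200 neurons generated with a 900 µm latent
decay length yields a fitted correlation length of ~770 µm (dichotomizing
the latent field compresses the decay slightly). The first neuron pair
carries ~0.03 bits of time-delayed information; against null systems with
the same TDMI its redundancy is 2.5 standard deviations above chance while
its synergy is typical — the signature of a spatially correlated pair.

A command-line interface mirrors the stages
(`mesopid simulate|binarize|pid|normalize|profiles|networks|compare|run-all`);
`mesopid run-all --config config.yaml` executes the full pipeline from a
YAML description of the datasets.

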