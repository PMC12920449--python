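import numpy as np
import pandas as pd
import pytest

import mesopid as m
from mesopid import spatial
from oracles import lambda_eff_quadrature


def synthetic_profile(c0, c_inf, lam, n_bins=15, noise_sd=0.0, seed=0):
    centers = np.geomspace(100, 3000, n_bins)
    rng = np.random.default_rng(seed)
    values = spatial.decay_model(centers, c0, c_inf, lam) + rng.normal(
        0, noise_sd, n_bins
    )
    return spatial.DistanceProfile(
        bin_edges_um=np.geomspace(90, 3100, n_bins + 1),
        bin_centers_um=centers,
        mean_value=values,
        sem=np.full(n_bins, max(noise_sd, 1e-4)),
        n_pairs=np.full(n_bins, 100),
    )


class TestPairwisePearson:
    def test_identical_and_complementary_columns(self):
        pop = m.generate_population(3, 1000, 1000, seed=1)
        x = np.tile([0, 1, 1, 0], 50)
        act = np.column_stack([x, x, 1 - x])
        pairs = m.pairwise_pearson(act, pop)
        lookup = {(r.i, r.j): r.value for r in pairs.itertuples()}
        assert lookup[(0, 1)] == pytest.approx(1.0)
        assert lookup[(0, 2)] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self, rng):
        pop = m.generate_population(4, 1000, 1000, seed=2)
        act = (rng.random((20_000, 4)) < 0.3).astype(float)
        pairs = m.pairwise_pearson(act, pop)
        assert np.abs(pairs["value"]).max() < 0.03

    def test_zero_variance_neurons_excluded(self, rng):
        pop = m.generate_population(3, 1000, 1000, seed=3)
        act = (rng.random((500, 3)) < 0.3).astype(float)
        act[:, 1] = 0.0
        pairs = m.pairwise_pearson(act, pop)
        assert set(zip(pairs["i"], pairs["j"])) == {(0, 2)}

    def test_all_zero_variance_rejected(self):
        pop = m.generate_population(2, 1000, 1000, seed=4)
        with pytest.raises(ValueError):
            m.pairwise_pearson(np.zeros((100, 2)), pop)


class TestBinByDistance:
    def test_single_distance_single_bin(self):
        table = pd.DataFrame(
            {"distance_um": np.full(20, 500.0), "value": np.arange(20.0)}
        )
        profile = m.bin_by_distance(table, 100, 3000, n_bins=5, min_pairs=1)
        assert profile.mean_value.size == 1
        assert profile.mean_value[0] == pytest.approx(np.arange(20.0).mean())

    def test_bin_assignment_matches_hand_computed_edges(self):
        # edges are 100 * 30**(k/4) for 4 bins over [100, 3000]
        edges = 100 * 30 ** (np.arange(5) / 4)
        distances = np.array([150.0, 300.0, 800.0, 2500.0, 120.0, 130.0])
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 9.0])
        table = pd.DataFrame({"distance_um": distances, "value": values})
        profile = m.bin_by_distance(table, 100, 3000, n_bins=4, min_pairs=1)
        np.testing.assert_allclose(profile.bin_edges_um, edges)
        # hand-binned: [150,120,130]->bin0, [300]->bin1, [800]->bin2, [2500]->bin3
        np.testing.assert_allclose(
            profile.mean_value, [np.mean([1, 5, 9]), 2.0, 3.0, 4.0]
        )

    def test_sem_of_identical_values_is_zero(self):
        table = pd.DataFrame(
            {"distance_um": np.full(10, 500.0), "value": np.full(10, 2.5)}
        )
        profile = m.bin_by_distance(table, 100, 3000, n_bins=3, min_pairs=1)
        assert profile.sem[0] == 0.0

    def test_log_bins_require_positive_dmin(self):
        table = pd.DataFrame({"distance_um": [10.0], "value": [1.0]})
        with pytest.raises(ValueError):
            m.bin_by_distance(table, 0.0, 3000)


class TestFitExponentialDecay:
    def test_noiseless_recovery(self):
        profile = synthetic_profile(0.05, 0.01, 500.0)
        fit = m.fit_exponential_decay(profile)
        assert fit.fit_ok
        assert fit.c0 == pytest.approx(0.05, rel=1e-6)
        assert fit.c_inf == pytest.approx(0.01, rel=1e-6)
        assert fit.lambda_um == pytest.approx(500.0, rel=1e-6)

    def test_noisy_recovery_within_20_percent(self):
        for seed in range(5):
            profile = synthetic_profile(0.05, 0.01, 500.0, noise_sd=0.002, seed=seed)
            fit = m.fit_exponential_decay(profile)
            assert fit.lambda_um == pytest.approx(500.0, rel=0.2)

    def test_constant_profile_flagged(self):
        profile = synthetic_profile(0.03, 0.03, 500.0)
        fit = m.fit_exponential_decay(profile)
        assert not fit.fit_ok
        assert "unidentifiable_lambda" in fit.flags

    def test_lambda_ordering_recovered_end_to_end(self):
        """Longer generating decay lengths give larger fitted lengths."""
        wins = 0
        for seed in range(5):
            fitted = {}
            for lam in (400.0, 900.0):
                pop = m.generate_population(150, 3000, 3000, seed=seed)
                act = m.generate_correlated_activity(
                    pop,
                    m.ActivityParams(
                        lambda_true_um=lam, n_frames=5000, seed=seed + 50
                    ),
                )
                pairs = m.pairwise_pearson(act, pop, 100.0)
                profile = m.bin_by_distance(pairs, min_pairs=20)
                fitted[lam] = m.fit_exponential_decay(profile).lambda_um
            wins += fitted[900.0] > fitted[400.0]
        assert wins >= 4

    def test_null_data_shows_no_spurious_structure(self):
        pop = m.generate_population(100, 3000, 3000, seed=9)
        act = m.generate_correlated_activity(
            pop,
            m.ActivityParams(
                c0_latent=0.0, c_inf_latent=0.0, n_frames=5000, seed=10
            ),
        )
        pairs = m.pairwise_pearson(act, pop, 100.0)
        profile = m.bin_by_distance(pairs, min_pairs=20)
        fit = m.fit_exponential_decay(profile)
        # no long-range structure: the fitted curve is flat beyond the
        # shortest distances (or the fit is flagged outright)
        if fit.fit_ok:
            curve = fit.predict(np.linspace(300.0, 3000.0, 50))
            assert np.ptp(curve) < 0.005


class TestNormalizeProfile:
    def test_model_curve_endpoints(self):
        fit = m.fit_exponential_decay(synthetic_profile(0.05, 0.01, 500.0))
        assert (fit.predict(0.0) - fit.c_inf) / (fit.c0 - fit.c_inf) == pytest.approx(1.0)
        at_lambda = (fit.predict(fit.lambda_um) - fit.c_inf) / (fit.c0 - fit.c_inf)
        assert at_lambda == pytest.approx(np.exp(-1.0), abs=1e-9)

    def test_affine_invariance(self):
        profile = synthetic_profile(0.05, 0.01, 500.0, noise_sd=0.001, seed=3)
        fit = m.fit_exponential_decay(profile)
        base = m.normalize_profile(profile, fit)
        rescaled = spatial.DistanceProfile(
            profile.bin_edges_um,
            profile.bin_centers_um,
            4.0 * profile.mean_value + 0.2,
            4.0 * profile.sem,
            profile.n_pairs,
        )
        refit = m.fit_exponential_decay(rescaled)
        renorm = m.normalize_profile(rescaled, refit)
        np.testing.assert_allclose(renorm.mean_value, base.mean_value, atol=1e-4)

    def test_degenerate_normalization_rejected(self):
        profile = synthetic_profile(0.05, 0.01, 500.0)
        fit = m.fit_exponential_decay(profile)
        flat = spatial.DecayFit(
            c0=0.02, c_inf=0.02, lambda_um=500.0,
            covariance=fit.covariance, fit_ok=True,
            residuals=fit.residuals,
        )
        with pytest.raises(ZeroDivisionError):
            m.normalize_profile(profile, flat)


class TestEffectiveLength:
    def make_fit(self, c0, c_inf, lam):
        return spatial.DecayFit(
            c0=c0, c_inf=c_inf, lambda_um=lam,
            covariance=np.zeros((3, 3)), fit_ok=True, residuals=np.zeros(1),
        )

    def test_reference_value(self):
        eff = m.effective_information_length(self.make_fit(1.0, 0.0, 1000.0))
        expected = 1000.0 * (np.exp(-0.1) - np.exp(-1.5))
        assert eff.lambda_eff_um == pytest.approx(expected, rel=1e-9)
        assert eff.lambda_eff_um == pytest.approx(681.7, abs=0.05)

    def test_constant_curve_returns_span(self):
        eff = m.effective_information_length(self.make_fit(0.02, 0.02, 700.0))
        assert eff.lambda_eff_um == pytest.approx(1400.0, rel=1e-12)

    def test_flat_limit_large_lambda(self):
        eff = m.effective_information_length(self.make_fit(0.05, 0.0, 1e9))
        assert eff.lambda_eff_um == pytest.approx(1400.0, rel=1e-6)

    def test_quadrature_matches_closed_form_and_oracle(self, rng):
        for _ in range(30):
            c0 = rng.uniform(0.01, 1.0)
            c_inf = rng.uniform(0.0, c0)
            lam = rng.uniform(50.0, 5000.0)
            fit = self.make_fit(c0, c_inf, lam)
            eff = m.effective_information_length(fit).lambda_eff_um
            closed = spatial.lambda_eff_closed_form(c0, c_inf, lam, 100.0, 1500.0)
            assert eff == pytest.approx(closed, rel=1e-9)
            assert eff == pytest.approx(
                lambda_eff_quadrature(c0, c_inf, lam, 100.0, 1500.0), rel=1e-6
            )

    def test_zero_c0_rejected(self):
        with pytest.raises(ZeroDivisionError):
            m.effective_information_length(self.make_fit(0.0, 0.0, 500.0))
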