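"""GBLUP / RKHS / BayesB prediction models and the accuracy metric."""

import numpy as np
import pytest

from gsopt import (
    BayesBConfig,
    MarkerMatrix,
    PopSimConfig,
    TraitSimConfig,
    compute_grm,
    fit_predict_bayesb,
    fit_predict_gblup,
    fit_predict_rkhs,
    prediction_accuracy,
    simulate_population,
    simulate_trait,
)
from gsopt.models import _fit_kernel_model, gaussian_kernel


@pytest.fixture(scope="module")
def panel():
    markers, _ = simulate_population(
        PopSimConfig(n=50, m=300, k_subpops=1, fst=0.0, rng_seed=2)
    )
    return markers, compute_grm(markers)


class TestGBLUP:
    def test_noiseless_trait_recovered_in_sample(self, panel):
        markers, A = panel
        y, _ = simulate_trait(markers, TraitSimConfig(h2=1.0, rng_seed=4))
        fit = fit_predict_gblup(y, A, markers.sample_ids, markers.sample_ids)
        assert prediction_accuracy(fit.gebv_for(markers.sample_ids), y) >= 0.99

    def test_pure_noise_trait_gives_no_accuracy(self, panel):
        markers, A = panel
        train, test = markers.sample_ids[:35], markers.sample_ids[35:]
        rng = np.random.default_rng(9)
        correlations = []
        for _ in range(50):
            y = rng.normal(size=35)
            g_true = rng.normal(size=15)  # independent of everything
            fit = fit_predict_gblup(y, A, train, test)
            gebv = fit.gebv_for(test)
            if np.std(gebv) == 0:
                continue
            correlations.append(abs(np.corrcoef(gebv, g_true)[0, 1]))
        assert np.mean(correlations) <= 0.25  # mean |r| of noise at n=15 is ~0.21

    def test_matches_direct_mme_solver_at_fixed_ratio(self):
        """BLUP at a fixed variance ratio equals the directly inverted
        mixed-model equations."""
        markers, _ = simulate_population(
            PopSimConfig(n=30, m=150, k_subpops=1, fst=0.0, rng_seed=6)
        )
        A = compute_grm(markers)
        y, _ = simulate_trait(markers, TraitSimConfig(h2=0.5, rng_seed=7))
        train = markers.sample_ids[:22]
        test = markers.sample_ids[22:]
        fit = fit_predict_gblup(y[:22], A, train, test)
        delta = fit.extras["delta"]
        ridge = 1e-6
        # oracle: g_hat = A_pt (A_tt + delta I)^-1 (y - mu), mu by GLS
        a_tt = A.submatrix(train) + ridge * np.eye(22)
        v_inv = np.linalg.inv(a_tt + delta * np.eye(22))
        ones = np.ones(22)
        mu = (ones @ v_inv @ y[:22]) / (ones @ v_inv @ ones)
        g_hat = A.submatrix(test, train) @ v_inv @ (y[:22] - mu)
        np.testing.assert_allclose(fit.gebv_for(test), g_hat, atol=1e-8)
        assert fit.intercept == pytest.approx(mu, abs=1e-8)

    def test_gebvs_invariant_to_phenotype_shift(self, panel):
        markers, A = panel
        y, _ = simulate_trait(markers, TraitSimConfig(h2=0.5, rng_seed=5))
        train, test = markers.sample_ids[:35], markers.sample_ids[35:]
        base = fit_predict_gblup(y[:35], A, train, test)
        shifted = fit_predict_gblup(y[:35] + 100.0, A, train, test)
        np.testing.assert_allclose(shifted.gebv_for(test), base.gebv_for(test), atol=1e-6)

    def test_variances_nonnegative(self, panel):
        markers, A = panel
        y, _ = simulate_trait(markers, TraitSimConfig(h2=0.3, rng_seed=8))
        fit = fit_predict_gblup(y[:35], A, markers.sample_ids[:35], markers.sample_ids[35:])
        assert fit.genetic_variance >= 0 and fit.residual_variance >= 0


class TestRKHS:
    def test_kernel_is_psd_on_random_panels(self):
        for seed in range(20):
            markers, _ = simulate_population(
                PopSimConfig(n=25, m=100, k_subpops=2, fst=0.2, rng_seed=100 + seed)
            )
            kernel, _ = gaussian_kernel(markers)
            eigvals = np.linalg.eigvalsh(kernel)
            assert eigvals.min() >= -1e-10

    def test_infinite_bandwidth_collapses_to_training_mean(self, panel):
        markers, _ = panel
        y, _ = simulate_trait(markers, TraitSimConfig(h2=0.5, rng_seed=3))
        train, test = markers.sample_ids[:35], markers.sample_ids[35:]
        fit = fit_predict_rkhs(y[:35], markers, train, test, bandwidth=1e12)
        # K -> all-ones: genetic signal is a constant absorbed by the mean
        assert np.ptp(fit.gebv_for(test)) <= 1e-3 * np.ptp(y[:35])

    def test_substituting_a_for_k_reproduces_gblup_bitwise(self, panel):
        markers, A = panel
        y, _ = simulate_trait(markers, TraitSimConfig(h2=0.5, rng_seed=3))
        train, test = markers.sample_ids[:35], markers.sample_ids[35:]
        gblup = fit_predict_gblup(y[:35], A, train, test)
        via_kernel = _fit_kernel_model(
            "rkhs", np.asarray(y[:35], float), A.values, list(A.ids), train, test, 1e-6
        )
        assert all(gblup.gebv[s] == via_kernel.gebv[s] for s in test)

    def test_close_to_gblup_on_additive_trait(self):
        """The additive-trait accuracy gap between RKHS and GBLUP stays small."""
        markers, _ = simulate_population(
            PopSimConfig(n=150, m=600, k_subpops=1, fst=0.0, rng_seed=12)
        )
        A = compute_grm(markers)
        gaps = []
        for seed in range(8):
            y, g = simulate_trait(markers, TraitSimConfig(h2=0.5, rng_seed=200 + seed))
            train, test = markers.sample_ids[:110], markers.sample_ids[110:]
            acc_g = prediction_accuracy(
                fit_predict_gblup(y[:110], A, train, test).gebv_for(test), g[110:]
            )
            acc_r = prediction_accuracy(
                fit_predict_rkhs(y[:110], markers, train, test).gebv_for(test), g[110:]
            )
            gaps.append(abs(acc_g - acc_r))
        assert np.mean(gaps) <= 0.05


class TestBayesB:
    def test_all_in_limit_matches_gblup(self):
        """With pi -> 1 (every effect in) and the effect-variance prior pinned
        (df -> infinity), BayesB reduces to RR-BLUP and its GEBVs track GBLUP."""
        markers, _ = simulate_population(
            PopSimConfig(n=80, m=200, k_subpops=1, fst=0.0, rng_seed=2)
        )
        A = compute_grm(markers)
        y, _ = simulate_trait(markers, TraitSimConfig(h2=0.5, rng_seed=14))
        train, test = markers.sample_ids[:60], markers.sample_ids[60:]
        bayes = fit_predict_bayesb(
            y[:60], markers, train, test,
            BayesBConfig(n_iter=2000, burn_in=500, pi_nonzero=0.999, df=1e6, rng_seed=1),
        )
        gblup = fit_predict_gblup(y[:60], A, train, test)
        r = np.corrcoef(bayes.gebv_for(test), gblup.gebv_for(test))[0, 1]
        assert r >= 0.98

    def test_recovers_single_large_qtl(self):
        markers, _ = simulate_population(
            PopSimConfig(n=80, m=200, k_subpops=1, fst=0.0, rng_seed=2)
        )
        xc = markers.centered()
        train = markers.sample_ids[:60]
        hits = 0
        runs = 5
        for seed in range(runs):
            rng = np.random.default_rng(300 + seed)
            qtl = int(rng.integers(200))
            g = xc[:, qtl] * 2.0
            sigma_e = np.sqrt(np.var(g) * (1 - 0.8) / 0.8)
            y = g + rng.normal(0, sigma_e, size=80)
            fit = fit_predict_bayesb(
                y[:60], markers, train, markers.sample_ids[60:],
                BayesBConfig(n_iter=1500, burn_in=500, rng_seed=seed),
            )
            hits += int(np.argmax(fit.extras["posterior_inclusion"])) == qtl
        assert hits >= runs - 1

    def test_reproducible_under_seed(self, panel):
        markers, _ = panel
        y, _ = simulate_trait(markers, TraitSimConfig(h2=0.5, rng_seed=4))
        train, test = markers.sample_ids[:30], markers.sample_ids[30:]
        cfg = BayesBConfig(n_iter=1000, burn_in=200, rng_seed=5)
        a = fit_predict_bayesb(y[:30], markers, train, test, cfg)
        b = fit_predict_bayesb(y[:30], markers, train, test, cfg)
        assert all(a.gebv[s] == b.gebv[s] for s in test)

    def test_short_chain_rejected(self, panel):
        markers, _ = panel
        with pytest.raises(ValueError, match="chain"):
            fit_predict_bayesb(
                np.zeros(10), markers, markers.sample_ids[:10], markers.sample_ids[10:],
                BayesBConfig(n_iter=500),
            )


class TestPredictionAccuracy:
    def test_identical_vectors(self):
        assert prediction_accuracy([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_negated_vectors(self):
        assert prediction_accuracy([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_table(self):
        # r = cov / (sd_x sd_y) = (5/3) / (sqrt(2/3) * sqrt(38/9))
        expected = (5 / 3) / (np.sqrt(2 / 3) * np.sqrt(38 / 9))
        assert prediction_accuracy([1, 2, 3], [2, 4, 7]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9934, abs=5e-5)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            prediction_accuracy([1, 1, 1], [1, 2, 3])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            prediction_accuracy([1, 2], [1, 2])


def test_accuracy_grows_with_training_size():
    """More phenotyped individuals give better predictions on average for an
    additive trait — the backbone of the accuracy-vs-size curves."""
    markers, _ = simulate_population(
        PopSimConfig(n=120, m=500, k_subpops=1, fst=0.0, rng_seed=22)
    )
    A = compute_grm(markers)
    test = markers.sample_ids[100:]
    pool = markers.sample_ids[:100]
    diffs = []
    for seed in range(10):
        y, g = simulate_trait(markers, TraitSimConfig(h2=0.5, rng_seed=400 + seed))
        rng = np.random.default_rng(seed)
        y_s = dict(zip(markers.sample_ids, y))
        small = [pool[i] for i in rng.choice(100, size=10, replace=False)]
        large = [pool[i] for i in rng.choice(100, size=80, replace=False)]
        acc = {}
        for label, train in (("small", small), ("large", large)):
            fit = fit_predict_gblup([y_s[s] for s in train], A, train, test)
            acc[label] = prediction_accuracy(fit.gebv_for(test), g[100:])
        diffs.append(acc["large"] - acc["small"])
    assert np.mean(diffs) > 0
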