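"""Training-set criteria: CDmean (against a mixed-model-equation oracle),
CDMEAN2, Rscore (against a Monte-Carlo expected-correlation oracle) and the
gAvg_GRM family."""

import numpy as np
import pytest
from scipy import stats

from gsopt import (
    CriterionSpec,
    PopSimConfig,
    RelationshipMatrix,
    cdmean,
    cdmean2,
    gavg_grm,
    pca_scores,
    resolve_target_population,
    rscore,
    simulate_population,
)
from conftest import SIX_IDS, random_psd_kinship


def mme_cdmean_oracle(values, train_idx, target_idx, lam=1.0, ridge=1e-6):
    """CDmean from the full mixed-model equations, built and inverted directly."""
    n = values.shape[0]
    a_r = values + ridge * np.eye(n)
    t = len(train_idx)
    z = np.zeros((t, n))
    for row, i in enumerate(train_idx):
        z[row, i] = 1.0
    x = np.ones((t, 1))
    coeff = np.block([
        [x.T @ x, x.T @ z],
        [z.T @ x, z.T @ z + lam * np.linalg.inv(a_r)],
    ])
    c22 = np.linalg.inv(coeff)[1:, 1:]
    cd = (np.diag(a_r) - lam * np.diag(c22)) / np.diag(a_r)
    return float(np.mean(cd[list(target_idx)]))


class TestTargetResolution:
    def test_untargeted_cdmean_uses_remaining_set(self):
        spec = CriterionSpec("cdmean", "untargeted")
        cand = [f"i{k}" for k in range(1, 11)]
        res = resolve_target_population(spec, cand, cand[:4])
        assert res.target_ids == cand[4:]
        assert res.provenance == "remaining set"

    def test_untargeted_rscore_uses_candidate_set(self):
        spec = CriterionSpec("rscore", "untargeted")
        cand = [f"i{k}" for k in range(1, 11)]
        res = resolve_target_population(spec, cand, cand[:4])
        assert res.target_ids == cand

    def test_untargeted_avg_grm_minmax_uses_remaining(self):
        spec = CriterionSpec("avg_grm_minmax", "untargeted")
        cand = list("abcdef")
        res = resolve_target_population(spec, cand, ["a", "b"])
        assert res.target_ids == ["c", "d", "e", "f"]

    def test_targeted_uses_test_set(self):
        spec = CriterionSpec("cdmean", "targeted")
        res = resolve_target_population(spec, list("abcd"), ["a"], ["x", "y"])
        assert res.target_ids == ["x", "y"] and res.provenance == "test set"

    def test_targeted_avg_grm_self_is_an_error(self):
        with pytest.raises(ValueError, match="not possible"):
            CriterionSpec("avg_grm_self", "targeted")

    def test_avg_grm_weight_pairings_enforced(self):
        assert CriterionSpec("avg_grm").a == 1 and CriterionSpec("avg_grm").b == 0
        assert CriterionSpec("avg_grm_minmax").a == 1
        with pytest.raises(ValueError, match="weights"):
            CriterionSpec("avg_grm", a=2.0, b=0.0)


class TestCDmean:
    def test_unrelated_target_gets_zero(self):
        A = RelationshipMatrix(SIX_IDS, np.eye(6))
        assert cdmean(A, SIX_IDS[:3], SIX_IDS[3:], ridge=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_mme_oracle_on_random_toys(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            A = random_psd_kinship(rng)
            ours = cdmean(A, A.ids[:3], A.ids[3:])
            oracle = mme_cdmean_oracle(A.values, [0, 1, 2], [3, 4, 5])
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_in_unit_interval_and_monotone_under_supersets(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            A = random_psd_kinship(rng)
            small = cdmean(A, A.ids[:3], A.ids[4:])
            large = cdmean(A, A.ids[:4], A.ids[4:])
            assert 0.0 <= small < 1.0
            assert large >= small - 1e-12

    def test_permutation_invariant_in_id_order(self, toy_kinship):
        v1 = cdmean(toy_kinship, SIX_IDS[:3], SIX_IDS[3:])
        v2 = cdmean(toy_kinship, SIX_IDS[2::-1], SIX_IDS[:2:-1])
        assert v1 == pytest.approx(v2, abs=1e-14)

    def test_empty_sets_rejected(self, toy_kinship):
        with pytest.raises(ValueError):
            cdmean(toy_kinship, [], SIX_IDS[3:])


class TestCDmean2:
    def test_full_rank_equals_cdmean(self, toy_kinship):
        full = cdmean(toy_kinship, SIX_IDS[:3], SIX_IDS[3:])
        reduced = cdmean2(toy_kinship, SIX_IDS[:3], SIX_IDS[3:], n_components=6)
        assert reduced == pytest.approx(full, abs=1e-6)

    def test_rank_agreement_with_cdmean(self):
        markers, _ = simulate_population(
            PopSimConfig(n=100, m=500, k_subpops=3, fst=0.2, rng_seed=31)
        )
        from gsopt import compute_grm

        A = compute_grm(markers)
        ids = markers.sample_ids
        target = ids[80:]
        rng = np.random.default_rng(5)
        full, reduced = [], []
        for _ in range(50):
            train = [ids[i] for i in sorted(rng.choice(80, size=20, replace=False))]
            full.append(cdmean(A, train, target))
            reduced.append(cdmean2(A, train, target, n_components=20))
        rho = stats.spearmanr(full, reduced).statistic
        assert rho >= 0.9

    def test_monotone_under_supersets_in_fixed_basis(self):
        # in a fixed rank-k spectral basis (as the subset search uses it),
        # a training superset can only add information
        from gsopt.criteria import cd_from_scores

        rng = np.random.default_rng(17)
        for _ in range(50):
            A = random_psd_kinship(rng)
            evals, evecs = np.linalg.eigh(A.values + 1e-6 * np.eye(6))
            order = np.argsort(evals)[::-1][:4]
            q = evecs[:, order] * np.sqrt(evals[order])
            small = cd_from_scores(q, [0, 1, 2], [4, 5])
            large = cd_from_scores(q, [0, 1, 2, 3], [4, 5])
            assert large >= small - 1e-9


class TestRscore:
    def test_invariant_under_full_pc_substitution(self, small_structured_panel):
        markers, _ = small_structured_panel
        ids = markers.sample_ids
        train, target = ids[:20], ids[40:]
        on_markers = rscore(markers, train, target)
        on_scores = rscore(pca_scores(markers, markers.n), train, target)
        assert on_scores == pytest.approx(on_markers, abs=1e-6)

    def test_ranks_training_sets_like_monte_carlo_oracle(self):
        """Rscore must rank training sets like the simulated expected
        GEBV-phenotype correlation under its own prior (beta ~ N(0, I),
        residual variance = the ridge penalty)."""
        markers, _ = simulate_population(
            PopSimConfig(n=12, m=30, k_subpops=2, fst=0.2, rng_seed=11)
        )
        ids = markers.sample_ids
        xc = markers.centered()
        target_idx = np.arange(8, 12)
        target = [ids[i] for i in target_idx]
        rng = np.random.default_rng(7)
        analytic, simulated = [], []
        for _ in range(20):
            tr_idx = np.sort(rng.choice(8, size=5, replace=False))
            train = [ids[i] for i in tr_idx]
            analytic.append(rscore(markers, train, target))
            xt, xv = xc[tr_idx], xc[target_idx]
            h = xv @ xt.T @ np.linalg.inv(xt @ xt.T + np.eye(len(tr_idx)))
            reps = 5000
            beta = rng.normal(size=(30, reps))
            y_t = xt @ beta + rng.normal(size=(5, reps))
            y_v = xv @ beta + rng.normal(size=(4, reps))
            y_hat = h @ y_t
            num = ((y_hat - y_hat.mean(0)) * (y_v - y_v.mean(0))).sum(0)
            den = y_hat.std(0) * y_v.std(0) * y_hat.shape[0]
            ok = den > 0
            simulated.append(float(np.mean(num[ok] / den[ok])))
        rho = stats.spearmanr(analytic, simulated).statistic
        assert rho >= 0.8

    def test_duplicating_a_training_individual_never_hurts(self):
        markers, _ = simulate_population(
            PopSimConfig(n=10, m=40, k_subpops=1, fst=0.0, rng_seed=19)
        )
        xc = markers.centered()
        ids = list(range(10))
        base_train, target = [0, 1, 2], [7, 8, 9]
        base = rscore(xc, base_train, target, sample_ids=ids)
        for dup in base_train:
            grown = rscore(
                np.vstack([xc, xc[dup]]),
                base_train + [10],
                target,
                sample_ids=ids + [10],
            )
            assert grown >= base - 1e-9

    def test_degenerate_identical_rows_rejected(self):
        x = np.ones((5, 4))
        with pytest.raises(ValueError, match="degenerate|identical"):
            rscore(x, [0, 1], [3, 4], sample_ids=list(range(5)))


class TestGavgGRM:
    A = RelationshipMatrix(
        ["1", "2", "3"],
        np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]]),
    )

    @pytest.mark.parametrize(
        "a, b, expected",
        [(1.0, 0.0, 0.15), (0.0, 1.0, -0.75), (1.0, 1.0, -0.60)],
    )
    def test_direct_arithmetic(self, a, b, expected):
        value = gavg_grm(self.A, ["1", "2"], ["3"], a, b)
        assert value == pytest.approx(expected, abs=1e-12)

    def test_a_zero_ignores_target(self):
        v1 = gavg_grm(self.A, ["1", "2"], ["3"], 0.0, 1.0)
        v2 = gavg_grm(self.A, ["1", "2"], ["1", "2", "3"], 0.0, 1.0)
        assert v1 == v2

    def test_singleton_training_self_weight(self):
        assert gavg_grm(self.A, ["2"], [], 0.0, 1.0) == pytest.approx(-1.0)

    def test_linear_in_weights(self, toy_kinship):
        rng = np.random.default_rng(23)
        for _ in range(20):
            a, b = rng.uniform(0, 3, size=2)
            train, target = SIX_IDS[:3], SIX_IDS[3:]
            combined = gavg_grm(toy_kinship, train, target, a, b)
            parts = a * gavg_grm(toy_kinship, train, target, 1.0, 0.0) + b * gavg_grm(
                toy_kinship, train, target, 0.0, 1.0
            )
            assert combined == pytest.approx(parts, abs=1e-12)

    def test_positive_a_needs_target(self, toy_kinship):
        with pytest.raises(ValueError, match="target"):
            gavg_grm(toy_kinship, SIX_IDS[:2], [], 1.0, 0.0)
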