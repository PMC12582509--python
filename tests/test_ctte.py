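import numpy as np
import pytest
from scipy.spatial.distance import cdist

import spikete as sp
from spikete.ctte import (
    EstimatorParams,
    TieError,
    conditional_ais_increment,
    conditional_te_rate,
    knn_log_density_ratio_sum,
)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            EstimatorParams(k_global=0)
        with pytest.raises(ValueError):
            EstimatorParams(nu_multiplier=0)
        with pytest.raises(ValueError):
            EstimatorParams(norm="manhattan")


class TestKnnCore:
    def brute_force_terms(self, X, U, k):
        dx = cdist(X, X, metric="chebyshev")
        np.fill_diagonal(dx, np.inf)
        rho = np.sort(dx, axis=1)[:, k - 1]
        du = cdist(X, U, metric="chebyshev")
        nu = np.sort(du, axis=1)[:, k - 1]
        return X.shape[1] * np.log(nu / rho)

    @pytest.mark.parametrize("n,d,k", [(50, 1, 4), (50, 3, 4), (100, 2, 7)])
    def test_matches_naive_all_pairs_exactly(self, n, d, k):
        rng = np.random.default_rng(n + d + k)
        X = rng.normal(size=(n, d))
        U = rng.normal(size=(2 * n, d))
        np.testing.assert_array_equal(
            knn_log_density_ratio_sum(X, U, k),
            self.brute_force_terms(X, U, k),
        )

    def test_exponential_kl_closed_form(self):
        # KL(Exp(1) || Exp(2)) = ln 2 - 1/2; the kNN estimate at n=2000, k=4
        # must agree within three standard errors of the estimate
        rng = np.random.default_rng(0)
        x = rng.exponential(1.0, 2000)
        u = rng.exponential(0.5, 2000)
        terms = knn_log_density_ratio_sum(x, u, k=4)
        kl = terms.mean() + np.log(len(u) / (len(x) - 1))
        se = terms.std(ddof=1) / np.sqrt(terms.size)
        assert abs(kl - (np.log(2) - 0.5)) < 3 * se

    def test_gaussian_2d_kl_closed_form(self):
        # KL(N(0, I) || N(mu, S)) with mu = (1, 0), S = diag(2, 1/2)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2000, 2))
        u = rng.normal(size=(2000, 2)) * np.sqrt([2.0, 0.5]) + [1.0, 0.0]
        true = 0.5 * (
            (1 / 2 + 2) + 1 / 2 * 1 - 2 + np.log(2 * 0.5)
        )
        terms = knn_log_density_ratio_sum(x, u, k=4)
        kl = terms.mean() + np.log(len(u) / (len(x) - 1))
        se = terms.std(ddof=1) / np.sqrt(terms.size)
        assert abs(kl - true) < 3 * se

    def test_identical_object_rejected(self):
        X = np.random.default_rng(2).normal(size=(20, 2))
        with pytest.raises(ValueError, match="distinct"):
            knn_log_density_ratio_sum(X, X, 4)

    def test_duplicates_raise_tie_error(self):
        X = np.zeros((10, 2))
        with pytest.raises(TieError):
            knn_log_density_ratio_sum(X, np.random.default_rng(3).normal(size=(20, 2)), 2)

    def test_k_too_large(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            knn_log_density_ratio_sum(rng.normal(size=(5, 1)), rng.normal(size=(9, 1)), 5)


@pytest.fixture(scope="module")
def poisson_pair():
    rng = np.random.default_rng(42)
    a = sp.poisson_train(10, 60, rng, "a")
    b = sp.poisson_train(10, 60, rng, "b")
    return sp.Recording.from_trains([a, b], 0, 60)


@pytest.fixture(scope="module")
def coupled_pair():
    # source b excites target a: extra a-spikes ~5 ms after each b spike
    rng = np.random.default_rng(43)
    b = sp.poisson_train(10, 60, rng, "b")
    base = sp.poisson_train(5, 60, rng, "a").times
    extra = b.times + 0.005 + rng.normal(0, 0.002, b.times.size)
    extra = extra[rng.random(extra.size) < 0.6]
    t = np.unique(np.concatenate([base, extra]))
    a = sp.SpikeTrain("a", t[(t > 0) & (t < 60)])
    return sp.Recording.from_trains([a, b], 0, 60)


class TestConditionalTE:
    def test_fields_and_invariants(self, poisson_pair):
        est = conditional_te_rate(
            poisson_pair, "a", "b", rng=np.random.default_rng(0)
        )
        assert est.surrogate_rates.size == 100
        assert est.bias_corrected_rate == est.rate - est.surrogate_rates.mean()
        assert abs(est.bias_corrected_surrogates.mean()) < 1e-12
        assert 0 <= est.p_empirical <= 1 and 0 <= est.p_normal <= 1
        assert est.per_spike_terms.size == est.n_x

    def test_independent_pair_not_significant(self, poisson_pair):
        est = conditional_te_rate(
            poisson_pair, "a", "b", rng=np.random.default_rng(1)
        )
        assert est.p_empirical > 0.05

    def test_coupled_pair_detected(self, coupled_pair):
        est = conditional_te_rate(
            coupled_pair, "a", "b", rng=np.random.default_rng(2)
        )
        assert est.p_empirical < 0.05
        assert est.bias_corrected_rate > 0

    def test_time_scaling_covariance(self, poisson_pair):
        # doubling all timestamps leaves per-spike terms bit-identical and
        # exactly halves the rate (the estimate is per unit time)
        est1 = conditional_te_rate(
            poisson_pair, "a", "b", rng=np.random.default_rng(3)
        )
        scaled = sp.Recording.from_trains(
            [sp.SpikeTrain(tr.unit_id, tr.times * 2.0) for tr in poisson_pair.trains],
            t_start=0.0, t_end=120.0,
        )
        est2 = conditional_te_rate(scaled, "a", "b", rng=np.random.default_rng(3))
        np.testing.assert_array_equal(est2.per_spike_terms, est1.per_spike_terms)
        assert est2.rate == pytest.approx(est1.rate / 2.0, rel=1e-12)

    def test_time_translation_invariance(self, poisson_pair):
        est1 = conditional_te_rate(
            poisson_pair, "a", "b", rng=np.random.default_rng(4)
        )
        shifted = sp.Recording.from_trains(
            [sp.SpikeTrain(tr.unit_id, tr.times + 5.0) for tr in poisson_pair.trains],
            t_start=5.0, t_end=65.0,
        )
        est2 = conditional_te_rate(shifted, "a", "b", rng=np.random.default_rng(4))
        np.testing.assert_allclose(est2.rate, est1.rate, rtol=1e-9)

    def test_variance_decreases_with_k_global(self):
        # a larger neighbour count lowers the estimator's variance
        rates = {k: [] for k in (2, 8)}
        for i in range(8):
            rng = np.random.default_rng(100 + i)
            a = sp.poisson_train(10, 30, rng, "a")
            b = sp.poisson_train(10, 30, rng, "b")
            rec = sp.Recording.from_trains([a, b], 0, 30)
            for k in rates:
                est = conditional_te_rate(
                    rec, "a", "b",
                    params=EstimatorParams(k_global=k, n_surrogates=5),
                    rng=np.random.default_rng(i),
                )
                rates[k].append(est.rate)
        assert np.var(rates[8]) < np.var(rates[2])


class TestAISIncrement:
    def test_joint_dimension_is_marginal_plus_one(self, poisson_pair):
        est = conditional_ais_increment(
            poisson_pair, "a", 2, rng=np.random.default_rng(5)
        )
        assert est.spec.target_depth == 2
        assert not est.spec.source_depths

    def test_poisson_target_has_no_storage(self):
        # memoryless process: the first-interval increment is not significant
        hits = 0
        for i in range(10):
            rng = np.random.default_rng(200 + i)
            a = sp.poisson_train(10, 60, rng, "a")
            rec = sp.Recording.from_trains([a], 0, 60)
            est = conditional_ais_increment(rec, "a", 1, rng=np.random.default_rng(i))
            hits += est.p_empirical < 0.05
        assert hits <= 2

    def test_refractory_renewal_target_has_storage(self):
        # Gamma(5) ISIs: the time since the last spike strongly modulates
        # the hazard, so the first interval carries storage
        hits = 0
        for i in range(10):
            rng = np.random.default_rng(300 + i)
            g = sp.gamma_renewal_train(5, 10, 60, rng, "g")
            rec = sp.Recording.from_trains([g], 0, 60)
            est = conditional_ais_increment(rec, "g", 1, rng=np.random.default_rng(i))
            hits += est.p_empirical < 0.05
        assert hits >= 9

    def test_invalid_depth(self, poisson_pair):
        with pytest.raises(ValueError):
            conditional_ais_increment(poisson_pair, "a", 0)
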