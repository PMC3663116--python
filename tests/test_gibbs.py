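"""Slice sampler, log posterior, full conditionals and the Gibbs chain."""

import math

import numpy as np
import pytest
from scipy.stats import beta as beta_dist
from scipy.stats import gamma as gamma_dist
from scipy.stats import kstest, poisson

from burstkin import gibbs, synthesize
from burstkin.gibbs import GibbsState, HyperParams
from burstkin.pobe import KineticParams
from burstkin.preprocess import CountMatrix


def make_cm(counts, lengths=None, factors=None):
    counts = np.asarray(counts, dtype=np.int64)
    g, j = counts.shape
    return CountMatrix(
        counts=counts,
        gene_ids=tuple(f"g{i}" for i in range(g)),
        gene_lengths=np.full(g, 1000.0) if lengths is None else np.asarray(lengths, float),
        cell_ids=tuple(f"c{k}" for k in range(j)),
        norm_factors=None if factors is None else np.asarray(factors, float),
    )


class TestSliceSample:
    def test_symmetric_beta_target(self):
        rng = np.random.default_rng(0)

        def logf(p):
            if p <= 0 or p >= 1:
                return -np.inf
            return math.log(p) + math.log(1 - p)  # Beta(2, 2)

        x = 0.5
        draws = np.empty(100_000)
        for i in range(draws.size):
            x = gibbs.slice_sample(logf, x, width=0.3, rng=rng)
            draws[i] = x
        assert draws.mean() == pytest.approx(0.5, abs=0.01)

    def test_gamma_target_moments(self):
        rng = np.random.default_rng(1)

        def logf(v):
            if v <= 0:
                return -np.inf
            return 2.0 * math.log(v) - v / 2.0  # Gamma(shape 3, scale 2), mean 6

        x = 1.0
        draws = np.empty(50_000)
        for i in range(draws.size):
            x = gibbs.slice_sample(logf, x, width=4.0, rng=rng)
            draws[i] = x
        # autocorrelated chain: allow ~6x the iid standard error
        se = math.sqrt(12.0 / draws.size)
        assert abs(draws.mean() - 6.0) < 6 * se

    def test_deterministic_given_seed(self):
        def logf(v):
            return -0.5 * v * v

        out = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            x = 0.0
            seq = [x := gibbs.slice_sample(logf, x, width=1.0, rng=rng) for _ in range(20)]
            out.append(seq)
        assert out[0] == out[1]

    def test_nonfinite_start_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            gibbs.slice_sample(lambda v: -np.inf, 0.0, width=1.0, rng=rng)


class TestLogPosterior:
    def one_gene_state(self):
        cm = make_cm([[0]], lengths=[1000.0], factors=[1.0])
        state = GibbsState(
            p=np.array([[0.5]]), kon=np.array([1.0]), koff=np.array([1.0]), s=np.array([2.0])
        )
        hyper = HyperParams(
            alpha_s=1.0, beta_s=np.array([1.0]), alpha_kon=1.0, beta_kon=1.0,
            alpha_koff=1.0, beta_koff=1.0,
        )
        return state, cm, hyper

    def test_single_cell_hand_value(self):
        # independent term-by-term evaluation with mpmath of the generative
        # density: Poisson(0 | 1*1*2*0.5) + Beta(0.5 | 1,1) + three unit
        # exponential priors at s=2, kon=1, koff=1
        import mpmath as mp

        state, cm, hyper = self.one_gene_state()
        lam = mp.mpf(2) * mp.mpf("0.5")
        expected = (
            (0 * mp.log(lam) - lam - mp.log(mp.factorial(0)))
            + (mp.log(mp.gamma(2) / (mp.gamma(1) * mp.gamma(1))))
            + (-mp.mpf(2) / 1 + 0 * mp.log(2) - 1 * mp.log(1) - mp.log(mp.gamma(1)))
            + (-mp.mpf(1) / 1 - mp.log(1) * 1 - mp.log(mp.gamma(1)))
            + (-mp.mpf(1) / 1 - mp.log(1) * 1 - mp.log(mp.gamma(1)))
        )
        assert gibbs.log_posterior(state, cm, hyper) == pytest.approx(
            float(expected), abs=1e-10
        )

    def test_duplicating_a_cell_doubles_data_terms(self):
        state1, cm1, hyper = self.one_gene_state()
        cm2 = make_cm([[0, 0]], lengths=[1000.0], factors=[1.0, 1.0])
        state2 = GibbsState(
            p=np.array([[0.5, 0.5]]), kon=np.array([1.0]), koff=np.array([1.0]),
            s=np.array([2.0]),
        )
        lp1 = gibbs.log_posterior(state1, cm1, hyper)
        lp2 = gibbs.log_posterior(state2, cm2, hyper)
        prior = -2.0 - 1.0 - 1.0  # the three exponential priors, shared
        assert lp2 - prior == pytest.approx(2 * (lp1 - prior), abs=1e-10)

    def test_always_finite_for_interior_p(self):
        rng = np.random.default_rng(3)
        cm = make_cm(rng.poisson(5, (4, 6)), factors=np.ones(6))
        state = GibbsState(
            p=rng.uniform(0.01, 0.99, (4, 6)),
            kon=rng.uniform(0.1, 10, 4),
            koff=rng.uniform(0.1, 10, 4),
            s=rng.uniform(1, 100, 4),
        )
        assert np.isfinite(gibbs.log_posterior(state, cm, HyperParams()))

    def test_boundary_p_rejected(self):
        state, cm, hyper = self.one_gene_state()
        state.p[0, 0] = 1.0
        with pytest.raises(ValueError):
            gibbs.log_posterior(state, cm, hyper)


class TestFullConditionals:
    def test_p_conditional_matches_direct_density_ratio(self):
        kon, koff, lam, x = 0.7, 2.3, 40.0, 13
        for pa, pb in [(0.2, 0.7), (0.05, 0.9), (0.5, 0.51)]:
            direct = (
                beta_dist(kon, koff).logpdf(pa)
                + poisson(lam * pa).logpmf(x)
                - beta_dist(kon, koff).logpdf(pb)
                - poisson(lam * pb).logpmf(x)
            )
            ours = gibbs.conditional_logdens_p(pa, x, lam, kon, koff) - gibbs.conditional_logdens_p(
                pb, x, lam, kon, koff
            )
            assert ours == pytest.approx(direct, abs=1e-9)

    def test_large_count_drives_p_toward_one(self):
        # x >> s: the conditional concentrates near the upper boundary
        rng = np.random.default_rng(6)
        x, lam, kon, koff = 500, 100.0, 1.0, 1.0
        cur = 0.5
        draws = np.empty(1000)
        for i in range(draws.size):
            cur = gibbs.slice_sample(
                lambda p: gibbs.conditional_logdens_p(p, x, lam, kon, koff),
                cur,
                width=0.2,
                rng=rng,
            )
            draws[i] = cur
        assert draws.mean() > 0.9

    def test_symmetric_prior_without_data_centers_p(self):
        # s -> 0 removes the count terms; with kon = koff the conditional is
        # the symmetric beta
        rng = np.random.default_rng(7)
        cur = 0.3
        draws = np.empty(20_000)
        for i in range(draws.size):
            cur = gibbs.slice_sample(
                lambda p: gibbs.conditional_logdens_p(p, 0, 1e-12, 2.0, 2.0),
                cur,
                width=0.3,
                rng=rng,
            )
            draws[i] = cur
        assert draws.mean() == pytest.approx(0.5, abs=0.02)

    def test_s_conditional_matches_conjugate_gamma(self):
        # with p and the switching rates held fixed, the s conditional is
        # exactly Gamma(alpha + sum x, scale 1/(1/beta + sum t p)); the slice
        # sampler's marginal must match a direct sampler of that law
        alpha, beta = 1.0, 50.0
        sum_x, sum_tp = 37.0, 4.2
        shape = alpha + sum_x
        scale = 1.0 / (1.0 / beta + sum_tp)
        rng = np.random.default_rng(8)
        cur = 5.0
        draws = np.empty(10_000)
        for i in range(draws.size):
            cur = gibbs.slice_sample(
                lambda s: gibbs.conditional_logdens_s(s, alpha, beta, sum_x, sum_tp),
                cur,
                width=3.0,
                rng=rng,
            )
            draws[i] = cur
        ks = kstest(draws, gamma_dist(shape, scale=scale).cdf).statistic
        assert ks < 0.02


class TestRunGibbs:
    def test_same_seed_bit_identical(self):
        cm = synthesize.simulate_dataset(
            [KineticParams(0.5, 1.0, 80.0)] * 3, 8, seed=1
        )
        a = gibbs.run_gibbs(cm, n_iter=100, seed=9)
        b = gibbs.run_gibbs(cm, n_iter=100, seed=9)
        assert np.array_equal(a.kon, b.kon)
        assert np.array_equal(a.log_posterior, b.log_posterior)
        assert np.array_equal(a.p_mean, b.p_mean)

    def test_recovers_rank_order_of_kon(self):
        rng = np.random.default_rng(10)
        params = synthesize.sample_parameter_grid(
            20, kon_range=(0.05, 5.0), koff_range=(0.05, 5.0), s=100.0, seed=30
        )
        cm = synthesize.simulate_dataset(params, 60, seed=31)
        chain = gibbs.run_gibbs(cm, n_iter=1500, seed=32)
        est = gibbs.point_estimates(chain)
        from scipy.stats import spearmanr

        truth = np.array([q.kon for q in params])
        assert spearmanr(truth, est.kon).statistic >= 0.8

    def test_log_posterior_trace_has_no_post_burnin_trend(self):
        # the trace has long memory (lag-200 autocorrelation ~0.3 on data
        # like this), so the batch size must be much larger than that for
        # the batch-means SE to be honest
        cm = synthesize.simulate_dataset(
            synthesize.sample_parameter_grid(5, (0.1, 1.0), (0.1, 1.0), 100.0, seed=40),
            20,
            seed=41,
        )
        chain = gibbs.run_gibbs(cm, n_iter=8000, seed=42)
        tail = chain.log_posterior[4000:]
        half = tail.size // 2
        a, b = tail[:half], tail[-half:]

        def batch_se(v, nb=4):
            m = v[: (v.size // nb) * nb].reshape(nb, -1).mean(axis=1)
            return m.std(ddof=1) / math.sqrt(nb)

        z = (a.mean() - b.mean()) / math.hypot(batch_se(a), batch_se(b))
        assert abs(z) < 4.0

    def test_error_on_too_few_iterations(self):
        cm = make_cm([[1]], factors=[1.0])
        with pytest.raises(ValueError):
            gibbs.run_gibbs(cm, n_iter=1, seed=0)


class TestPointEstimates:
    def _chain(self, kon):
        n, g = kon.shape
        return gibbs.GibbsChain(
            kon=kon,
            koff=kon + 1.0,
            s=kon + 2.0,
            log_posterior=np.zeros(n),
            p_mean=np.full((g, 1), 0.5),
            n_iter=n,
            seed=0,
        )

    def test_constant_chain_returns_constant(self):
        chain = self._chain(np.full((100, 2), 3.0))
        est = gibbs.point_estimates(chain)
        assert est.kon == pytest.approx([3.0, 3.0])
        assert est.kon_se == pytest.approx([0.0, 0.0])

    def test_thinning_consistency(self):
        cm = synthesize.simulate_dataset([KineticParams(0.3, 0.6, 90.0)] * 4, 30, seed=50)
        chain = gibbs.run_gibbs(cm, n_iter=2000, seed=51)
        est = gibbs.point_estimates(chain)
        thin = chain.kon[chain.default_burn_in :: 2]
        assert np.allclose(thin.mean(axis=0), est.kon, rtol=0.1)

    def test_burn_in_choice_stable_on_converged_chain(self):
        cm = synthesize.simulate_dataset([KineticParams(0.5, 0.5, 100.0)] * 3, 40, seed=60)
        chain = gibbs.run_gibbs(cm, n_iter=3000, seed=61)
        full = gibbs.point_estimates(chain, burn_in=0)
        half = gibbs.point_estimates(chain)
        # agreement within 5 MC standard errors per gene
        tol = 5 * np.maximum(half.kon_se, 1e-6)
        assert np.all(np.abs(full.kon - half.kon) < np.maximum(tol, 0.3 * half.kon))

    def test_empty_post_burnin_rejected(self):
        chain = self._chain(np.full((10, 1), 1.0))
        with pytest.raises(ValueError):
            gibbs.point_estimates(chain, burn_in=10)


class TestPriorSensitivity:
    def test_diffuse_prior_changes_identifiable_estimates_little(self):
        params = [KineticParams(0.2, 0.4, 120.0), KineticParams(0.5, 0.8, 150.0)]
        cm = synthesize.simulate_dataset(params, 60, seed=70)
        base = gibbs.point_estimates(
            gibbs.run_gibbs(cm, hyper=HyperParams(), n_iter=2000, seed=71)
        )
        diffuse = gibbs.point_estimates(
            gibbs.run_gibbs(
                cm,
                hyper=HyperParams(beta_kon=10_000.0, beta_koff=10_000.0),
                n_iter=2000,
                seed=71,
            )
        )
        assert np.all(np.abs(diffuse.kon - base.kon) / base.kon < 0.2)
        assert np.all(np.abs(diffuse.s - base.s) / base.s < 0.2)
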