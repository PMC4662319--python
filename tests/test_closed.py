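"""Closed-population model: cells, p*, the N update, and fitting."""

import numpy as np
import pytest
from scipy.special import expit, gammaln
from scipy.stats import chisquare

import latentmark as lm
from latentmark.closed import (
    _pstar_fast,
    closed_cell_logprob,
    compute_pstar,
    update_N,
)


class TestCells:
    def test_history_20_hand_value(self):
        """History 20, T=2, p=0.5, delta2=0.4: p1*d2*(1-p2) = 0.1."""
        lp = closed_cell_logprob((2, 0), np.array([0.5, 0.5]), 0.3, 0.4, 0.0)
        assert np.isclose(np.exp(lp), 0.1)

    def test_history_43(self):
        p = np.array([0.6, 0.7])
        d1, d2, a = 0.2, 0.3, 0.4
        lp = closed_cell_logprob((4, 3), p, d1, d2, a)
        both = 1 - d1 - d2
        expected = p[0] * both * a * p[1] * both * (1 - a)
        assert np.isclose(np.exp(lp), expected)

    def test_branch_sum_identity(self, rng):
        p = rng.uniform(size=10_000)
        d1 = rng.uniform(size=10_000)
        d2 = (1 - d1) * rng.uniform(size=10_000)
        a = rng.uniform(size=10_000)
        total = ((1 - p) + p * d1 + p * d2
                 + p * (1 - d1 - d2) * (1 - a) + p * (1 - d1 - d2) * a)
        assert np.max(np.abs(total - 1)) < 1e-12


class TestPstar:
    def test_two_occasion_half(self):
        assert np.isclose(compute_pstar(np.zeros(2)), 0.75)

    def test_closed_form_matches_product(self, rng):
        eta = rng.normal(size=5)
        expected = 1 - np.prod(1 - expit(eta))
        assert np.isclose(compute_pstar(eta), expected)

    def test_heterogeneity_integral_vs_monte_carlo(self, rng):
        eta = np.zeros(3)
        s2 = 1.0
        got = compute_pstar(eta, s2)
        z = rng.normal(0, 1, size=1_000_000)
        mc = 1 - np.prod(1 - expit(eta[None, :] + z[:, None]), axis=1).mean()
        se = np.std(1 - np.prod(1 - expit(eta[None, :] + z[:, None]), axis=1)) / 1000
        assert abs(got - mc) < 3 * se + 1e-4

    def test_fast_path_agrees_with_quadrature(self, rng):
        for _ in range(5):
            eta = rng.normal(scale=1.5, size=4)
            s2 = float(rng.uniform(0.01, 9.0))
            assert np.isclose(compute_pstar(eta, s2), _pstar_fast(eta, s2),
                              atol=1e-8)

    def test_monotone_in_detection(self, rng):
        eta = rng.normal(size=4)
        assert compute_pstar(eta + 0.3) > compute_pstar(eta)

    def test_invalid_variance(self):
        with pytest.raises(ValueError):
            compute_pstar(np.zeros(2), -1.0)


class TestUpdateN:
    def test_requires_detections(self, rng):
        with pytest.raises(ValueError):
            update_N(0, 0.5, rng)

    def test_certain_detection_returns_n(self, rng):
        assert update_N(10, 1.0, rng) == 10

    def test_conditional_mean_identity(self, rng):
        draws = np.array([update_N(10, 0.5, rng) for _ in range(20_000)])
        # E[N] = n + n(1-p*)/p* = 20
        assert abs(draws.mean() - 20) < 0.25

    @pytest.mark.parametrize("n,pstar", [(5, 0.3), (10, 0.5), (20, 0.8)])
    def test_matches_grid_posterior(self, n, pstar, rng):
        """Draw frequencies match the normalized posterior
        (1/N) C(N,n) (1-p*)^(N-n) p*^n."""
        draws = np.array([update_N(n, pstar, rng) for _ in range(100_000)])
        Ns = np.arange(n, max(draws.max(), n + 10) + 1)
        logw = (-np.log(Ns) + gammaln(Ns + 1) - gammaln(Ns - n + 1)
                - gammaln(n + 1) + (Ns - n) * np.log(1 - pstar)
                + n * np.log(pstar))
        w = np.exp(logw - logw.max())
        w /= w.sum()
        # bin the tail so expected counts stay >= 5
        counts = np.bincount(draws - n, minlength=len(Ns))[: len(Ns)]
        exp_counts = w * draws.size
        keep = exp_counts >= 5
        obs = np.append(counts[keep], counts[~keep].sum())
        exp = np.append(exp_counts[keep], exp_counts[~keep].sum())
        stat, pval = chisquare(obs, exp * obs.sum() / exp.sum())
        assert pval > 1e-3


class TestFitClosed:
    def test_single_mark_matches_grid_oracle(self):
        sim = lm.simdata_closed(lm.SimConfig(N=60, noccas=4, pbeta=-0.5,
                                             delta_1=1.0, delta_2=0.0,
                                             alpha=0.0, data_type="never"),
                                seed=31)
        obsmat = sim.observed_matrix
        n, T = obsmat.shape
        ndet = int((obsmat > 0).sum())

        def logpost(b, N):
            p = expit(b)
            ps = 1 - (1 - p) ** T
            return (ndet * np.log(p) + (n * T - ndet) * np.log(1 - p)
                    + gammaln(N + 1) - gammaln(N - n + 1) - gammaln(n + 1)
                    + (N - n) * np.log(1 - ps) - np.log(N)
                    - 0.5 * b**2 / 1.75)

        bs = np.linspace(-2.5, 1.0, 71)
        Ns = np.arange(n, 1500)
        lp = np.array([[logpost(b, N) for N in Ns] for b in bs])
        w = np.exp(lp - lp.max())
        w /= w.sum()
        e_b = (w.sum(1) * bs).sum()
        e_N = (w.sum(0) * Ns).sum()

        fit = lm.mark_closed(obsmat, iter=8000, burnin=2000, chains=2, seed=32)
        assert abs(fit.param("pbeta[(Intercept)]").mean() - e_b) < 0.06
        assert abs(fit.param("N").mean() - e_N) < 1.5

    def test_default_monitored_parameters(self):
        sim = lm.simdata_closed(lm.SimConfig(N=40, noccas=4, delta_1=0.4,
                                             delta_2=0.4, alpha=0.0,
                                             data_type="never"), seed=33)
        fit = lm.fit_closed(sim.observed_matrix, data_type="never",
                            iter=600, burnin=200, seed=34)
        assert fit.names == ["pbeta[(Intercept)]", "N", "delta_1", "delta_2"]

    def test_N_never_below_n(self):
        sim = lm.simdata_closed(lm.SimConfig(N=40, noccas=4, delta_1=0.4,
                                             delta_2=0.4, alpha=0.0,
                                             data_type="never"), seed=35)
        fit = lm.fit_closed(sim.observed_matrix, data_type="never",
                            iter=1500, burnin=300, seed=36, parms="all")
        sh = fit.extras["slot_hist"].reshape(fit.nchains * fit.ndraws, -1)
        n_per_draw = (sh >= 0).sum(axis=1)
        assert np.all(fit.param("N").ravel() >= n_per_draw)

    def test_alpha_fixed_for_never(self):
        sim = lm.simdata_closed(lm.SimConfig(N=40, noccas=4, delta_1=0.4,
                                             delta_2=0.4, alpha=0.0,
                                             data_type="never"), seed=37)
        fit = lm.fit_closed(sim.observed_matrix, data_type="never",
                            iter=500, burnin=100, seed=38)
        assert "alpha" not in fit.names
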