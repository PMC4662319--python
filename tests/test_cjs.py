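"""CJS model: cell probabilities, sweep exactness, fitting interface."""

import numpy as np
import pytest
from scipy.special import ndtr

import latentmark as lm
from latentmark.cjs import cjs_cell_logprob, cjs_history_logprob


class TestCellProbabilities:
    def setup_method(self):
        self.p = np.array([0.3, 0.45, 0.6])
        self.phi = np.array([0.8, 0.7])
        self.pars = dict(delta1=0.25, delta2=0.45, alpha=0.4)

    def test_history_020_alive_branch(self):
        """History 020, T=3: first capture at occasion 2; occasion 3 factor
        is (1-p3) phi2 when alive, (1-phi2) when dead."""
        lp_alive = cjs_cell_logprob((0, 2, 0), self.p, self.phi,
                                    **self.pars, q=(0, 1, 1))
        assert np.isclose(np.exp(lp_alive), (1 - self.p[2]) * self.phi[1])
        lp_dead = cjs_cell_logprob((0, 2, 0), self.p, self.phi,
                                   **self.pars, q=(0, 1, 0))
        assert np.isclose(np.exp(lp_dead), 1 - self.phi[1])

    def test_history_412(self):
        lp = cjs_cell_logprob((4, 1, 2), self.p, self.phi, **self.pars)
        expected = (self.p[1] * self.pars["delta1"] * self.phi[0]
                    * self.p[2] * self.pars["delta2"] * self.phi[1])
        assert np.isclose(np.exp(lp), expected)

    def test_history_103(self):
        lp = cjs_cell_logprob((1, 0, 3), self.p, self.phi, **self.pars)
        d1, d2, a = self.pars.values()
        expected = ((1 - self.p[1]) * self.phi[0]
                    * self.p[2] * (1 - d1 - d2) * (1 - a) * self.phi[1])
        assert np.isclose(np.exp(lp), expected)

    def test_marginal_tail_is_chi_recursion(self):
        lp = cjs_cell_logprob((2, 0, 0), self.p, self.phi, **self.pars)
        chi2 = (1 - self.phi[1]) + self.phi[1] * (1 - self.p[2])
        chi1 = (1 - self.phi[0]) + self.phi[0] * (1 - self.p[1]) * chi2
        assert np.isclose(np.exp(lp), chi1)

    def test_first_capture_type_factor(self):
        lp_cell = cjs_cell_logprob((4, 1, 2), self.p, self.phi, **self.pars)
        lp_hist = cjs_history_logprob((4, 1, 2), self.p, self.phi, **self.pars)
        d1, d2, a = self.pars.values()
        assert np.isclose(lp_hist - lp_cell, np.log((1 - d1 - d2) * a))

    def test_last_occasion_first_capture_informs_types_only(self):
        lp = cjs_history_logprob((0, 0, 2), self.p, self.phi, **self.pars)
        assert np.isclose(np.exp(lp), self.pars["delta2"])

    def test_branch_probabilities_sum_to_one(self, rng):
        """(1-p) + p d1 + p d2 + p(1-d1-d2)(1-a) + p(1-d1-d2)a = 1."""
        p = rng.uniform(size=10_000)
        d1 = rng.uniform(size=10_000)
        d2 = (1 - d1) * rng.uniform(size=10_000)
        a = rng.uniform(size=10_000)
        total = ((1 - p) + p * d1 + p * d2
                 + p * (1 - d1 - d2) * (1 - a) + p * (1 - d1 - d2) * a)
        assert np.max(np.abs(total - 1.0)) < 1e-12


class TestGibbsExactness:
    def test_single_mark_posterior_matches_grid_oracle(self):
        """Probit CJS without heterogeneity on single-mark data must match
        the exact posterior computed on a (beta_p, beta_phi) grid."""
        sim = lm.simdata_cjs(lm.SimConfig(N=50, noccas=4, pbeta=-0.2,
                                          phibeta=0.9, delta_1=1.0,
                                          delta_2=0.0, alpha=0.0,
                                          data_type="never"), seed=21)
        obsmat = sim.observed_matrix
        T = 4

        def loglik(bp, bphi):
            p = ndtr(np.full(T, bp))
            phi = ndtr(np.full(T - 1, bphi))
            ll = 0.0
            for row in obsmat:
                det = np.flatnonzero(row > 0)
                C0, L0 = det[0], det[-1]
                cell = 1.0
                for t0 in range(C0 + 1, L0 + 1):
                    cell *= p[t0] * phi[t0 - 1] if row[t0] else (1 - p[t0]) * phi[t0 - 1]
                chi = 1.0
                for t0 in range(T - 1, L0, -1):
                    chi = (1 - phi[t0 - 1]) + phi[t0 - 1] * (1 - p[t0]) * chi
                ll += np.log(cell * chi)
            return ll

        bps = np.linspace(-2.0, 1.2, 65)
        bphis = np.linspace(-1.5, 3.0, 91)
        lp = np.array([[loglik(bp, bphi) - 0.5 * bp**2 / 1.75
                        - 0.5 * bphi**2 / 1.75 for bphi in bphis] for bp in bps])
        w = np.exp(lp - lp.max())
        w /= w.sum()
        e_bp = (w.sum(1) * bps).sum()
        e_bphi = (w.sum(0) * bphis).sum()

        fit = lm.mark_cjs(obsmat, iter=8000, burnin=2000, chains=2, seed=22)
        got_bp = fit.param("pbeta[(Intercept)]").mean()
        got_bphi = fit.param("phibeta[(Intercept)]").mean()
        assert abs(got_bp - e_bp) < 0.08
        assert abs(got_bphi - e_bphi) < 0.12

    def test_q_all_one_when_fully_detected(self):
        mat = np.ones((6, 4), dtype=int)
        fit = lm.mark_cjs(mat, iter=400, burnin=100, seed=23, parms="all")
        # every individual detected at every occasion: survival to T certain,
        # so phibeta posterior is pushed up strongly
        assert fit.param("phibeta[(Intercept)]").mean() > 0.5


class TestFitInterface:
    def test_monitor_requires_model_term(self):
        sim = lm.simdata_cjs(lm.SimConfig(N=30, noccas=4), seed=24)
        with pytest.raises(ValueError):
            lm.fit_cjs(sim.observed_matrix, data_type="sometimes",
                       mod_phi="~1", parms=("phibeta", "sigma2_zphi"),
                       iter=200, burnin=50)

    def test_iter_burnin_validation(self):
        sim = lm.simdata_cjs(lm.SimConfig(N=30, noccas=4), seed=24)
        with pytest.raises(ValueError):
            lm.fit_cjs(sim.observed_matrix, data_type="sometimes",
                       iter=100, burnin=100)

    def test_reproducible_given_seed(self):
        sim = lm.simdata_cjs(lm.SimConfig(N=30, noccas=4), seed=25)
        f1 = lm.fit_cjs(sim.observed_matrix, data_type="sometimes",
                        iter=400, burnin=100, seed=9)
        f2 = lm.fit_cjs(sim.observed_matrix, data_type="sometimes",
                        iter=400, burnin=100, seed=9)
        np.testing.assert_array_equal(f1.chains, f2.chains)

    def test_no_type2_evidence_pushes_delta2_down(self):
        sim = lm.simdata_cjs(lm.SimConfig(N=60, noccas=5, delta_1=1.0,
                                          delta_2=0.0, alpha=0.0,
                                          data_type="never"), seed=26)
        fit = lm.fit_cjs(sim.observed_matrix, data_type="never",
                         mod_delta="~type", iter=2000, burnin=500, seed=27,
                         parms=("delta",))
        assert fit.param("delta_2").mean() < 0.05
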