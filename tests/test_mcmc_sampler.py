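"""Sampler correctness: conjugate updates, prior recovery, diagnostics,
determinism."""

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist, kstest

import scsm
from scsm.mcmc_sampler import (SamplerConfig, _ChainWorkspace, batch_means_mcse,
                               gelman_rubin, monte_carlo_error_check,
                               update_precision_conjugate)
from scsm.scsm_model import ModelState, PriorSpec


def _path3():
    return scsm.AdjacencyStructure(area_ids=["a", "b", "c"],
                                   edges=np.array([[0, 1], [1, 2]]))


class TestConjugatePrecision:
    def test_zero_iid_field_returns_prior_with_shifted_shape(self):
        rng = np.random.default_rng(0)
        draws = [update_precision_conjugate(np.zeros(6), None, (0.1, 0.1), rng)
                 for _ in range(20000)]
        # posterior = Gamma(0.1 + 3, 0.1)
        ks = kstest(draws, gamma_dist(3.1, scale=1 / 0.1).cdf)
        assert ks.pvalue > 0.01

    def test_path_graph_closed_form_parameters(self):
        # x=(0,1,3): edge sum 5, dof = 3-1 = 2 -> Gamma(0.1+1, 0.1+2.5)
        rng = np.random.default_rng(1)
        adj = _path3()
        x = np.array([0.0, 1.0, 3.0])
        draws = np.array([update_precision_conjugate(x, adj, (0.1, 0.1), rng)
                          for _ in range(100_000)])
        a, b = 1.1, 2.6
        assert np.isclose(draws.mean(), a / b, atol=3 * np.sqrt(a / b ** 2 / len(draws)))
        ks = kstest(draws, gamma_dist(a, scale=1 / b).cdf)
        assert ks.pvalue > 0.001

    def test_icar_case_uses_component_corrected_dof(self, four_cycle):
        rng = np.random.default_rng(2)
        x = np.array([1.0, -1.0, 1.0, -1.0])
        # two of the four cycle edges differ by 2: pairwise sum = 8; dof = 3
        draws = np.array([update_precision_conjugate(x, four_cycle, (0.1, 0.1), rng)
                          for _ in range(50000)])
        a, b = 0.1 + 1.5, 0.1 + 4.0
        assert np.isclose(draws.mean(), a / b, rtol=0.05)


class TestPriorRecovery:
    def test_constrained_icar_prior_marginals(self, four_cycle):
        """With the likelihood switched off and the precision held fixed, the
        sampled theta marginals match the sum-to-zero ICAR distribution
        (covariance = Laplacian pseudoinverse / tau)."""
        n = four_cycle.n
        areas = scsm.AreaTable(area_ids=four_cycle.area_ids,
                               observed=np.zeros((n, 2)),
                               expected=np.ones((n, 2)))
        st = ModelState.zeros(n)
        tau = 2.0
        st.tau_theta = tau
        ws = _ChainWorkspace(st, areas, four_cycle, PriorSpec(),
                             likelihood_weight=0.0)
        rng = np.random.default_rng(0)
        draws = []
        for it in range(30000):
            ws.sweep(rng)
            if it % 3 == 0:
                draws.append(ws.state.theta.copy())
        emp = np.cov(np.array(draws)[500:].T)
        W = four_cycle.dense()
        L = np.diag(W.sum(1)) - W
        w, V = np.linalg.eigh(L)
        oracle = (V[:, 1:] / w[1:]) @ V[:, 1:].T / tau
        assert np.allclose(emp, oracle, atol=0.02)

    def test_single_area_poisson_lognormal_quadrature(self):
        """One area, only u1 free: posterior mean of u1 matches 1-D
        quadrature of the Poisson-lognormal density."""
        from scipy.integrate import quad
        adj = scsm.AdjacencyStructure(area_ids=["a"], edges=np.empty((0, 2)))
        areas = scsm.AreaTable(area_ids=["a"], observed=[[3, 0]],
                               expected=[[2.0, 1e-300]])
        st = ModelState.zeros(1)
        tau_u1 = 4.0
        st.tau_u = np.array([tau_u1, 1e8])
        ws = _ChainWorkspace(st, areas, adj, PriorSpec(), likelihood_weight=1.0)
        ws.scales[:] = 1e-12   # freeze everything ...
        ws.scales[3] = 0.8     # ... except u1
        rng = np.random.default_rng(1)
        us = []
        for it in range(60000):
            ws.sweep(rng)
            if it % 3 == 0:
                us.append(ws.state.u[0, 0])
        us = np.array(us[1000:])
        f = lambda x: np.exp(3 * (np.log(2) + x) - 2 * np.exp(x)
                             - 0.5 * tau_u1 * x * x)
        Z = quad(f, -6, 6)[0]
        mean = quad(lambda x: x * f(x), -6, 6)[0] / Z
        mcse = us.std() / np.sqrt(len(us) / 20)  # crude ESS deflation
        assert abs(us.mean() - mean) < 4 * mcse + 0.01

    def test_intercept_recovery_with_fields_fixed(self):
        """With all random effects held at truth, the intercept posterior
        concentrates at its generative value."""
        cfg = scsm.SyntheticConfig(nrows=6, ncols=6, alpha=(0.4, -0.2), seed=3)
        data = scsm.simulate_dataset(cfg)
        ws = _ChainWorkspace(data.truth, data.areas, data.adjacency,
                             PriorSpec(), likelihood_weight=1.0)
        ws.scales[:] = 1e-12
        ws.scales[5] = ws.scales[6] = 0.05
        rng = np.random.default_rng(0)
        alphas = []
        for it in range(20000):
            ws.sweep(rng)
            if it % 5 == 0:
                alphas.append(ws.state.alpha.copy())
        alphas = np.array(alphas[400:])
        # posterior sd of an intercept ~ 1/sqrt(total expected count)
        se = 1.0 / np.sqrt(data.areas.expected.sum(axis=0))
        assert np.all(np.abs(alphas.mean(axis=0) - [0.4, -0.2]) < 4 * se)


class TestRunChains:
    def test_determinism_identical_seeds(self, small_dataset):
        cfg = SamplerConfig(n_chains=2, burn_in=200, retained=200, thin=10, seed=9)
        a = scsm.run_chains(small_dataset.areas, small_dataset.adjacency,
                            PriorSpec(), cfg)
        b = scsm.run_chains(small_dataset.areas, small_dataset.adjacency,
                            PriorSpec(), cfg)
        for key in a.params:
            assert np.array_equal(a.params[key], b.params[key])

    def test_draw_bookkeeping_at_reference_protocol(self):
        """At the reference protocol (10,000 retained, thin 100, 2 chains)
        the stored sample count is 200; checked at reduced burn-in on a tiny
        lattice."""
        cfg10 = scsm.SyntheticConfig(nrows=3, ncols=3, seed=1)
        data = scsm.simulate_dataset(cfg10)
        cfg = SamplerConfig(n_chains=2, burn_in=500, retained=10_000, thin=100,
                            seed=2)
        out = scsm.run_chains(data.areas, data.adjacency, PriorSpec(), cfg)
        assert out.n_draws == 200
        assert out.params["theta"].shape == (2, 100, 9)

    def test_convergence_on_lattice(self):
        """Two dispersed chains agree (all BGR < 1.1) on a 10x10 synthetic
        lattice with well-identified known parameters, at desk-scale chain
        lengths."""
        cfg10 = scsm.SyntheticConfig(nrows=10, ncols=10, seed=4, delta=1.0,
                                     mean_expected=(30.0, 30.0),
                                     tau_u=(8.0, 8.0))
        data = scsm.simulate_dataset(cfg10)
        cfg = SamplerConfig(n_chains=2, burn_in=20_000, retained=10_000,
                            thin=50, seed=11)
        out = scsm.run_chains(data.areas, data.adjacency, PriorSpec(), cfg)
        assert out.rhat is not None
        assert float(out.rhat["rhat"].max()) < 1.1
        assert out.converged

    def test_sum_to_zero_constraint_on_draws(self, fitted_samples):
        theta = fitted_samples.pooled("theta")
        s = fitted_samples.pooled("s")
        assert np.allclose(theta.sum(axis=1), 0.0, atol=1e-8)
        assert np.allclose(s.sum(axis=2), 0.0, atol=1e-8)

    def test_positive_precision_draws(self, fitted_samples):
        assert np.all(fitted_samples.pooled("tau_theta") > 0)
        assert np.all(fitted_samples.pooled("tau_s") > 0)
        assert np.all(fitted_samples.pooled("tau_u") > 0)

    def test_sensitivity_priors_run(self, small_dataset):
        cfg = SamplerConfig(n_chains=2, burn_in=300, retained=300, thin=30, seed=5)
        out = scsm.run_chains(small_dataset.areas, small_dataset.adjacency,
                              PriorSpec.sensitivity(), cfg)
        sd_s = 1 / np.sqrt(out.pooled("tau_s"))
        assert np.all((sd_s > 0) & (sd_s < 10))


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        r = gelman_rubin(np.stack([x, x]))
        assert abs(r - 1.0) < 0.01

    def test_iid_chains_approach_one(self):
        rng = np.random.default_rng(1)
        r = gelman_rubin(rng.normal(size=(2, 20000)))
        assert abs(r - 1.0) < 0.02

    def test_separated_chains_large(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert gelman_rubin(chains) > 3.0

    def test_matches_arviz_oracle(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        # AR(1) chains so between/within variances genuinely differ
        x = np.zeros((2, 2000))
        for c in range(2):
            for t in range(1, 2000):
                x[c, t] = 0.7 * x[c, t - 1] + rng.normal()
        ours = gelman_rubin(x)
        theirs = float(np.asarray(
            az.rhat(az.convert_to_dataset(x[:, :, None]))["x"].values).ravel()[0])
        # arviz uses rank-normalized split-R-hat; agreement is approximate
        assert abs(ours - theirs) < 0.05

    def test_single_chain_error(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestMonteCarloError:
    def test_iid_passes_for_adequate_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        mcse = batch_means_mcse(x)
        assert mcse < 0.05 * x.std()
        # and roughly equals sd/sqrt(n)
        assert np.isclose(mcse, x.std() / np.sqrt(x.size), rtol=0.6)

    def test_ar1_inflates_mcse(self):
        rng = np.random.default_rng(1)
        rho = 0.9
        n = 20000
        x = np.empty(n)
        x[0] = 0.0
        for t in range(1, n):
            x[t] = rho * x[t - 1] + rng.normal()
        mcse = batch_means_mcse(x, n_batches=40)
        sd = x.std()
        naive = sd / np.sqrt(n)
        # spectral inflation factor sqrt((1+rho)/(1-rho)) ~ 4.36
        inflation = np.sqrt((1 + rho) / (1 - rho))
        assert mcse > 2 * naive
        assert np.isclose(mcse, naive * inflation, rtol=0.5)

    def test_too_few_batches_error(self):
        with pytest.raises(ValueError):
            batch_means_mcse(np.arange(100.0), n_batches=5)

    def test_constant_chain_passes_with_flag(self, fitted_samples):
        frozen = scsm.PosteriorSamples(
            params={k: np.zeros_like(v) for k, v in fitted_samples.params.items()},
            area_ids=fitted_samples.area_ids, config=fitted_samples.config,
            seeds=fitted_samples.seeds)
        report = monte_carlo_error_check(frozen)
        assert report["passed"].all()

    def test_check_on_fitted_samples(self, fitted_samples):
        report = monte_carlo_error_check(fitted_samples)
        assert set(report.columns) == {"parameter", "mcse", "sd", "passed"}
        assert len(report) == 8
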