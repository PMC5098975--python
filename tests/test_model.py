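"""Likelihood, priors, gradients, fitting contracts and summaries."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from riiv.data import prepare_latent
from riiv.errors import DegenerateDataError, ParameterDomainError
from riiv.model import (
    DHGLM,
    MCMCSettings,
    ModelParams,
    PriorConfig,
    fit_full,
    fit_reduced,
    summarize,
    summarize_draws,
)
from riiv.simulate import SimConfig, simulate


def _zero_params(n_id, n_cell):
    return ModelParams(
        beta=np.zeros(6), gamma=np.zeros(3), sigma_id_mu=0.0, omega=0.0,
        rho=0.0, sigma_id_burst=0.0, u_mu=np.zeros(n_id),
        u_sigma=np.zeros(n_id), v_burst=np.zeros(n_cell),
    )


def _random_params(rng, n_id, n_cell):
    return ModelParams(
        beta=rng.normal(0, 0.5, 6),
        gamma=rng.normal(0, 0.3, 3),
        sigma_id_mu=rng.uniform(0.2, 0.8),
        omega=rng.uniform(0.1, 0.6),
        rho=rng.uniform(-0.8, 0.8),
        sigma_id_burst=rng.uniform(0.2, 0.8),
        u_mu=rng.normal(0, 0.5, n_id),
        u_sigma=rng.normal(0, 0.3, n_id),
        v_burst=rng.normal(0, 0.4, n_cell),
    )


def _tiny_prepared(rng, n_id=5, n_burst=2, reps=2):
    df, _ = simulate(
        SimConfig(n_id=n_id, n_burst=n_burst, reps_low=reps, reps_high=reps,
                  burst_dropout=0.0),
        seed=int(rng.integers(2 ** 31)),
    )
    return prepare_latent(df)


class TestLogLikelihood:
    def test_standard_normal_closed_form(self, rng):
        prep = _tiny_prepared(rng)
        model = DHGLM(prep)
        params = _zero_params(prep.n_id, prep.n_cell)
        prep.y[:] = 0.0
        prep.x_mean[:] = 0.0
        prep.x_resid[:] = 0.0
        expected = prep.n_obs * sps.norm.logpdf(0.0)
        assert model.log_likelihood(params) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_matches_bruteforce_rowwise_sum(self, rng):
        """The model's summed log density equals a per-row scipy oracle."""
        for _ in range(5):
            prep = _tiny_prepared(rng)
            model = DHGLM(prep)
            params = _random_params(rng, prep.n_id, prep.n_cell)
            mu, sd = model.predicted_moments(params)
            brute = sum(
                sps.norm.logpdf(prep.y[i], mu[i], sd[i])
                for i in range(prep.n_obs)
            )
            assert model.log_likelihood(params) == pytest.approx(
                brute, abs=1e-10
            )

    def test_decreases_for_overlarge_residual_sd(self, rng):
        prep = _tiny_prepared(rng)
        model = DHGLM(prep)
        values = []
        for g0 in (1.0, 2.0, 4.0, 8.0):
            p = _zero_params(prep.n_id, prep.n_cell)
            p.gamma = np.array([g0, 0.0, 0.0])
            values.append(model.log_likelihood(p))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_invariant_under_individual_relabelling(self, rng):
        prep = _tiny_prepared(rng)
        model = DHGLM(prep)
        params = _random_params(rng, prep.n_id, prep.n_cell)
        base = model.log_likelihood(params)
        perm = rng.permutation(prep.n_id)
        prep2_j = perm[prep.j_index]
        import copy

        prep2 = copy.deepcopy(prep)
        prep2.indices.j_index = prep2_j
        model2 = DHGLM(prep2)
        params2 = ModelParams(
            beta=params.beta, gamma=params.gamma,
            sigma_id_mu=params.sigma_id_mu, omega=params.omega,
            rho=params.rho, sigma_id_burst=params.sigma_id_burst,
            u_mu=params.u_mu[np.argsort(perm)],
            u_sigma=params.u_sigma[np.argsort(perm)],
            v_burst=params.v_burst,
        )
        assert model2.log_likelihood(params2) == pytest.approx(base,
                                                               abs=1e-10)

    def test_full_nests_reduced_at_matched_parameters(self, rng):
        """With omega = 0 and no rIIV effects the two likelihoods agree."""
        prep = _tiny_prepared(rng)
        full = DHGLM(prep, heterogeneous=True)
        reduced = DHGLM(prep, heterogeneous=False)
        params = _random_params(rng, prep.n_id, prep.n_cell)
        params.omega = 0.0
        params.rho = 0.0
        params.u_sigma = np.zeros(prep.n_id)
        assert full.log_likelihood(params) == pytest.approx(
            reduced.log_likelihood(params), abs=1e-12
        )


class TestLogPrior:
    def test_lkj2_peaks_at_independence(self, rng):
        prep = _tiny_prepared(rng)
        model = DHGLM(prep, priors=PriorConfig(lkj_eta=2.0))
        base = _random_params(rng, prep.n_id, prep.n_cell)
        base.u_mu = np.zeros(prep.n_id)
        base.u_sigma = np.zeros(prep.n_id)

        def at_rho(r):
            base.rho = r
            # isolate the correlation prior from the random-effect density
            mvn = sps.multivariate_normal.logpdf(
                np.zeros((prep.n_id, 2)), mean=np.zeros(2), cov=base.cov_id
            ).sum()
            return model.log_prior(base) - mvn

        assert at_rho(0.0) > at_rho(0.5) > at_rho(0.99)

    def test_lkj1_flat_in_correlation(self, rng):
        prep = _tiny_prepared(rng)
        model = DHGLM(prep, priors=PriorConfig(lkj_eta=1.0))
        p = _random_params(rng, prep.n_id, prep.n_cell)
        p.u_mu = np.zeros(prep.n_id)
        p.u_sigma = np.zeros(prep.n_id)

        def at_rho(r):
            p.rho = r
            # subtract the MVN(0, Omega) term, which depends on rho even
            # for zero effects through its normalizer
            from scipy.stats import multivariate_normal

            lp = model.log_prior(p)
            mvn = multivariate_normal.logpdf(
                np.zeros((prep.n_id, 2)), mean=np.zeros(2), cov=p.cov_id
            ).sum()
            return lp - mvn

        assert at_rho(0.0) == pytest.approx(at_rho(0.5), abs=1e-10)

    def test_rho_outside_open_interval_rejected(self, rng):
        prep = _tiny_prepared(rng)
        model = DHGLM(prep)
        p = _random_params(rng, prep.n_id, prep.n_cell)
        p.rho = 1.0
        with pytest.raises(ParameterDomainError):
            model.log_prior(p)


class TestGradients:
    @pytest.mark.parametrize("heterogeneous", [True, False])
    def test_analytic_gradient_matches_finite_differences(
        self, rng, heterogeneous
    ):
        prep = _tiny_prepared(rng)
        model = DHGLM(prep, heterogeneous=heterogeneous)
        theta = 0.3 * rng.standard_normal(model.dim)
        _, grad = model.logp_grad(theta)
        eps = 1e-6
        check = list(range(min(14, model.dim))) + [model._head, model.dim - 1]
        for i in check:
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (model.logp_grad(tp)[0] - model.logp_grad(tm)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestFitting:
    def test_single_individual_refused(self, rng):
        df, _ = simulate(SimConfig(n_id=1), seed=1)
        prep = prepare_latent(df)
        with pytest.raises(DegenerateDataError, match="two individuals"):
            fit_full(prep)

    def test_identical_seed_gives_identical_draws(self, rng):
        df, _ = simulate(SimConfig(n_id=6), seed=9)
        prep = prepare_latent(df)
        settings = MCMCSettings(chains=1, warmup=100, draws=50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = fit_full(prep, mcmc=settings, seed=7)
            b = fit_full(prep, mcmc=settings, seed=7)
        np.testing.assert_array_equal(a.draws["beta"], b.draws["beta"])
        np.testing.assert_array_equal(a.draws["u_sigma"], b.draws["u_sigma"])

    def test_posterior_structure_and_convergence_table(self, small_posterior):
        post = small_posterior
        assert post.draws["beta"].shape[-1] == 6
        assert post.pointwise_loglik.shape[:2] == post.draws["omega"].shape
        assert {"rhat", "ess_bulk", "ess_tail"} <= set(
            post.convergence.columns
        )
        assert "omega" in post.convergence.index

    def test_reduced_posterior_has_no_riiv_parameters(
        self, small_reduced_posterior
    ):
        post = small_reduced_posterior
        assert "omega" not in post.draws
        assert "rho" not in post.draws
        assert "u_sigma" not in post.draws
        assert "gamma0" in post.convergence.index

    def test_posterior_save_load_round_trip(self, tmp_path, small_posterior):
        from riiv.model import Posterior

        path = tmp_path / "post.npz"
        small_posterior.save(path)
        back = Posterior.load(path)
        np.testing.assert_array_equal(
            back.draws["omega"], small_posterior.draws["omega"]
        )
        np.testing.assert_array_equal(
            back.pointwise_loglik, small_posterior.pointwise_loglik
        )
        assert back.meta["model"] == "full"


class TestSummarize:
    def test_constant_draws_degenerate_interval(self):
        s = summarize_draws(np.full(100, 3.25))
        assert s["mean"] == 3.25
        assert s["lower"] == s["upper"] == 3.25

    def test_standard_normal_sample_interval(self, rng):
        draws = rng.standard_normal(100_000)
        s = summarize_draws(draws, level=0.95)
        assert s["mean"] == pytest.approx(0.0, abs=0.02)
        assert s["lower"] == pytest.approx(-1.96, abs=0.04)
        assert s["upper"] == pytest.approx(1.96, abs=0.04)

    def test_interval_commutes_with_monotone_transform(self, rng):
        normal = rng.normal(0.0, 1.0, 50_000)
        s_exp = summarize_draws(np.exp(normal), level=0.9)
        s_raw = summarize_draws(normal, level=0.9)
        # quantile interpolation between adjacent order statistics keeps
        # the commutation only approximate at finite sample size
        assert s_exp["lower"] == pytest.approx(np.exp(s_raw["lower"]),
                                               rel=1e-3)
        assert s_exp["upper"] == pytest.approx(np.exp(s_raw["upper"]),
                                               rel=1e-3)

    def test_summary_table_covers_all_scalars(self, small_posterior):
        table = summarize(small_posterior)
        assert len(table) == 13
        assert {"mean", "median", "lower", "upper"} <= set(table.columns)
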