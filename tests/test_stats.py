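"""Derived statistics: closed forms, study values, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riiv.errors import ParameterDomainError
from riiv.model import Posterior
from riiv.stats import (
    corr_from_cov,
    cv_p,
    derive_posterior,
    fold_ratio,
    repeatability_int,
    repeatability_long,
    repeatability_short,
)

# variance components as printed for the guppy activity analysis
SIGMA_ID = 0.51
SIGMA_BURST = 0.46
GAMMA0 = float(np.log(0.61))
OMEGA = 0.42
RHO = -0.34

positive = st.floats(0.05, 3.0, allow_nan=False)


class TestClosedForms:
    @pytest.mark.parametrize(
        "func,args,expected",
        [
            (repeatability_int, (SIGMA_ID, SIGMA_BURST), 0.55),
            (repeatability_short, (SIGMA_ID, SIGMA_BURST, GAMMA0), 0.56),
            (repeatability_long, (SIGMA_ID, SIGMA_BURST, GAMMA0), 0.31),
        ],
        ids=["R_int", "R_short", "R_long"],
    )
    def test_study_variance_components_reproduce_repeatabilities(
        self, func, args, expected
    ):
        assert round(float(func(*args)), 2) == expected

    @pytest.mark.parametrize(
        "func,args,expected",
        [
            (repeatability_int, (1.0, 0.0), 1.0),
            (repeatability_int, (0.0, 0.7), 0.0),
            (repeatability_short, (1.0, 1.0, 0.0), 2.0 / 3.0),
            (repeatability_short, (0.0, 0.0, 0.3), 0.0),
            (repeatability_long, (1.0, 0.0, 0.0), 0.5),
            (cv_p, (0.0,), 0.0),
            (fold_ratio, (0.0, 2.0), 1.0),
            (fold_ratio, (0.25, 2.0), np.exp(2.0)),
            (corr_from_cov, (0.0, 0.5, 0.4), 0.0),
            (corr_from_cov, (0.2, 0.5, 0.4), 1.0),
        ],
    )
    def test_boundary_and_unit_cases(self, func, args, expected):
        assert float(func(*args)) == pytest.approx(expected, abs=1e-12)

    def test_predictability_cv_at_study_omega(self):
        assert float(cv_p(OMEGA)) == pytest.approx(0.439, abs=5e-4)
        # interval endpoints transform monotonically from omega's interval
        assert round(float(cv_p(0.35)), 2) == 0.36
        assert round(float(cv_p(0.5)), 2) == 0.53

    def test_residual_variance_fold_at_two_sd(self):
        fold = float(fold_ratio(OMEGA, k=2.0, scale="variance"))
        assert fold == pytest.approx(np.exp(3.36), rel=1e-12)
        assert fold == pytest.approx(28.8, abs=0.05)
        assert float(fold_ratio(OMEGA, k=2.0, scale="sd")) == pytest.approx(
            np.exp(1.68), rel=1e-12
        )

    def test_mean_riiv_correlation_from_covariance(self):
        cov = RHO * SIGMA_ID * OMEGA
        assert float(corr_from_cov(cov, SIGMA_ID, OMEGA)) == pytest.approx(
            RHO, abs=1e-12
        )

    def test_domain_errors(self):
        with pytest.raises(ParameterDomainError):
            repeatability_int(0.0, 0.0)
        with pytest.raises(ParameterDomainError):
            cv_p(-0.1)
        with pytest.raises(ParameterDomainError):
            corr_from_cov(0.1, 0.0, 0.4)
        with pytest.raises(ParameterDomainError):
            corr_from_cov(0.9, 0.5, 0.4)  # implies |r| > 1


class TestInvariants:
    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(positive, positive, st.floats(-2.0, 2.0))
    def test_long_term_never_exceeds_other_repeatabilities(
        self, s_id, s_burst, g0
    ):
        r_int = float(repeatability_int(s_id, s_burst))
        r_short = float(repeatability_short(s_id, s_burst, g0))
        r_long = float(repeatability_long(s_id, s_burst, g0))
        assert 0.0 <= r_long <= min(r_int, r_short) + 1e-12
        assert r_short <= 1.0 and r_int <= 1.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(0.01, 1.5), st.floats(0.01, 1.5))
    def test_predictability_cv_strictly_increasing(self, a, b):
        lo, hi = sorted([a, b])
        if hi - lo > 1e-9:
            assert float(cv_p(hi)) > float(cv_p(lo))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0.01, 1.0), st.floats(0.5, 4.0), st.floats(0.5, 4.0))
    def test_fold_ratio_increasing_in_omega_and_k(self, om, k1, k2):
        lo, hi = sorted([k1, k2])
        if hi - lo > 1e-9:
            assert float(fold_ratio(om, hi)) > float(fold_ratio(om, lo))
        assert float(fold_ratio(om + 0.1, lo)) > float(fold_ratio(om, lo))

    def test_small_omega_limit_equals_omega(self):
        assert float(cv_p(0.01)) == pytest.approx(0.01, rel=1e-4)


def _synthetic_posterior(draws_dict):
    shaped = {k: np.asarray(v)[None, :] if np.asarray(v).ndim == 1
              else np.asarray(v) for k, v in draws_dict.items()}
    n = next(iter(shaped.values())).shape[1]
    return Posterior(
        draws=shaped,
        pointwise_loglik=np.zeros((1, n, 1)),
        convergence=pd.DataFrame(columns=["rhat", "ess_bulk", "ess_tail"]),
        converged=True,
        sampler_stats=[],
    )


class TestDerivePosterior:
    def test_degenerate_posterior_equals_plug_in(self):
        n = 50
        post = _synthetic_posterior(
            {
                "sigma_id_mu": np.full(n, SIGMA_ID),
                "sigma_id_burst": np.full(n, SIGMA_BURST),
                "gamma": np.tile([GAMMA0, 0.0, 0.0], (1, n, 1)).reshape(
                    1, n, 3
                ),
                "omega": np.full(n, OMEGA),
                "rho": np.full(n, RHO),
            }
        )
        derived = derive_posterior(post)
        for stat in ("R_int", "R_short", "R_long", "CV_P", "fold_ratio"):
            assert derived.summary.loc[stat, "mean"] == pytest.approx(
                derived.plug_in[stat], abs=1e-12
            )
            assert derived.summary.loc[stat, "lower"] == pytest.approx(
                derived.summary.loc[stat, "upper"], abs=1e-12
            )

    def test_cv_interval_is_transform_of_omega_interval(self, rng):
        n = 20_000
        om = np.abs(rng.normal(OMEGA, 0.03, n))
        post = _synthetic_posterior(
            {
                "sigma_id_mu": np.full(n, SIGMA_ID),
                "sigma_id_burst": np.full(n, SIGMA_BURST),
                "gamma": np.tile([GAMMA0, 0.0, 0.0], (n, 1))[None],
                "omega": om,
                "rho": np.full(n, RHO),
            }
        )
        derived = derive_posterior(post)
        lo, hi = np.quantile(om, [0.025, 0.975])
        assert derived.summary.loc["CV_P", "lower"] == pytest.approx(
            float(cv_p(lo)), rel=1e-6
        )
        assert derived.summary.loc["CV_P", "upper"] == pytest.approx(
            float(cv_p(hi)), rel=1e-6
        )

    def test_recovery_posterior_covers_generating_r_int(
        self, small_posterior, small_sim
    ):
        _, truth = small_sim
        t = truth.config.truth
        true_r = float(repeatability_int(t.sigma_id_mu, t.sigma_id_burst))
        derived = derive_posterior(small_posterior)
        assert (
            derived.summary.loc["R_int", "lower"]
            <= true_r
            <= derived.summary.loc["R_int", "upper"]
        )

    def test_rounded_report_table(self, small_posterior):
        derived = derive_posterior(small_posterior)
        table = derived.round_table(2)
        assert ((table["mean"] * 100) % 1 == 0).all()
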