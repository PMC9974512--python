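"""Closed-form Bayes factors: values, identities, limits, oracle agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import bff
from bff import (
    GammaNCPrior,
    NormalMomentPrior,
    TestReport,
    bf10,
    bf10_chisq,
    bf10_f,
    bf10_t,
    bf10_z,
    likelihood_ratio_curve,
    log_bf10_f,
    log_bf10_t,
    posterior_odds,
    quadrature_bf10,
)

finite_stats = st.floats(-10, 10, allow_nan=False)
positive_tau2 = st.floats(1e-3, 50, allow_nan=False)


class TestClosedForms:
    def test_z_example_value(self):
        # z = 2 with the J(0, 1.125) prior implied by n = 100, omega = 0.15
        assert bf10_z(2.0, 1.125) == pytest.approx(2.90, abs=0.005)

    def test_chisq_example_value(self):
        # h = 12.65 on 6 df with tau2 = 707 * 0.035^2
        assert bf10_chisq(12.65, 6, 707 * 0.035**2) == pytest.approx(3.07, abs=0.005)

    @pytest.mark.parametrize(
        "fn,args",
        [
            (bf10_z, (1.7,)),
            (bf10_t, (2.2, 30)),
            (bf10_chisq, (5.0, 3)),
            (bf10_f, (4.05, 2, 82)),
        ],
    )
    def test_tau2_zero_gives_exactly_one(self, fn, args):
        assert fn(*args, 0.0) == 1.0

    def test_chisq_at_zero_statistic(self):
        # h = 0 collapses the middle/exponential factors
        k, tau2 = 4, 0.9
        assert bf10_chisq(0.0, k, tau2) == pytest.approx((tau2 + 1) ** (-k / 2 - 1), rel=1e-12)

    @pytest.mark.parametrize("fn,args", [(bf10_z, ()), (bf10_t, (30,))])
    def test_sign_symmetry(self, fn, args):
        assert fn(2.3, *args, 1.4) == pytest.approx(fn(-2.3, *args, 1.4), rel=1e-15)

    def test_negative_tau2_rejected(self):
        with pytest.raises(ValueError):
            bf10_z(1.0, -0.1)

    def test_negative_statistic_rejected_for_chisq_and_f(self):
        with pytest.raises(ValueError):
            bf10_chisq(-1.0, 3, 0.5)
        with pytest.raises(ValueError):
            bf10_f(-1.0, 2, 30, 0.5)

    def test_no_overflow_at_extreme_df_and_statistics(self):
        assert np.isfinite(log_bf10_t(50.0, 10**6, 10.0))
        assert np.isfinite(log_bf10_f(50.0, 3, 10**6, 10.0))
        assert np.isfinite(log_bf10_t(50.0, 5, 100.0))

    @pytest.mark.parametrize(
        "fn,args",
        [
            (bf10_z, ()),
            (bf10_t, (25,)),
        ],
    )
    def test_monotone_in_absolute_statistic(self, fn, args):
        vals = [fn(x, *args, 1.5) for x in np.linspace(0, 8, 30)]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize(
        "fn,args",
        [
            (bf10_chisq, (4,)),
            (bf10_f, (3, 40)),
        ],
    )
    def test_monotone_in_nonnegative_statistic(self, fn, args):
        vals = [fn(x, *args, 1.5) for x in np.linspace(0, 40, 30)]
        assert np.all(np.diff(vals) > 0)


class TestInvarianceIdentities:
    """z and z^2 = chi2_1 tests (and t, t^2 = F_{1,nu}) give equal BFs."""

    @settings(derandomize=True, max_examples=100)
    @given(z=finite_stats, tau2=positive_tau2)
    def test_chisq_of_squared_z(self, z, tau2):
        assert bf10_chisq(z * z, 1, tau2) == pytest.approx(bf10_z(z, tau2), rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(t=finite_stats, tau2=positive_tau2, nu=st.integers(1, 500))
    def test_f_of_squared_t(self, t, tau2, nu):
        assert bf10_f(t * t, 1, nu, tau2) == pytest.approx(bf10_t(t, nu, tau2), rel=1e-12)


class TestLimits:
    def test_t_converges_to_z_at_large_nu(self):
        assert bf10_t(2.0, 10**6, 1.125) == pytest.approx(bf10_z(2.0, 1.125), rel=1e-3)

    def test_f_converges_to_chisq_at_large_m(self):
        h, k = 12.65, 6
        assert bf10_f(h / k, k, 10**5, 0.866) == pytest.approx(
            bf10_chisq(h, k, 0.866), rel=1e-3
        )


class TestQuadratureOracle:
    """The closed forms equal the prior-averaged density ratio by quadrature."""

    @pytest.mark.parametrize("z", [0.0, 1.0, 2.0, 3.0])
    @pytest.mark.parametrize("tau2", [0.1, 1.0, 10.0])
    def test_z_family(self, z, tau2):
        rep = TestReport("z", z, n=100)
        assert quadrature_bf10(rep, NormalMomentPrior(0.0, tau2)) == pytest.approx(
            bf10_z(z, tau2), rel=1e-6
        )

    @pytest.mark.parametrize("t,nu", [(0.5, 5), (2.2, 30), (3.0, 120)])
    @pytest.mark.parametrize("tau2", [0.5, 2.0])
    def test_t_family(self, t, nu, tau2):
        rep = TestReport("t", t, n=nu + 1, df2=nu)
        assert quadrature_bf10(rep, NormalMomentPrior(0.0, tau2)) == pytest.approx(
            bf10_t(t, nu, tau2), rel=1e-6
        )

    @pytest.mark.parametrize("h,k", [(0.5, 1), (5.0, 3), (12.65, 6)])
    @pytest.mark.parametrize("tau2", [0.5, 2.0])
    def test_chisq_family(self, h, k, tau2):
        rep = TestReport("chisq", h, df1=k, n=100)
        assert quadrature_bf10(rep, GammaNCPrior(k, tau2)) == pytest.approx(
            bf10_chisq(h, k, tau2), rel=1e-6
        )

    @pytest.mark.parametrize("f,k,m", [(1.99, 2, 137), (4.05, 2, 82), (0.5, 4, 20)])
    @pytest.mark.parametrize("tau2", [0.833, 2.0])
    def test_f_family(self, f, k, m, tau2):
        rep = TestReport("f", f, df1=k, df2=m, n=m + k + 1)
        assert quadrature_bf10(rep, GammaNCPrior(k, tau2)) == pytest.approx(
            bf10_f(f, k, m, tau2), rel=1e-6
        )

    def test_tau2_near_zero_approaches_one(self):
        rep = TestReport("z", 1.5, n=50)
        assert quadrature_bf10(rep, NormalMomentPrior(0.0, 1e-8)) == pytest.approx(
            1.0, abs=1e-3
        )

    def test_cross_validated_against_second_rule(self):
        # fixed-grid Simpson integration as an independent second rule
        z, tau2 = 1.5, 2.0
        prior = NormalMomentPrior(0.0, tau2)
        lam = np.linspace(-15 * math.sqrt(3 * tau2), 15 * math.sqrt(3 * tau2), 20001)
        m1 = integrate.simpson(stats.norm.pdf(z, loc=lam) * prior.pdf(lam), x=lam)
        simpson_bf = m1 / stats.norm.pdf(z)
        assert simpson_bf == pytest.approx(bf10_z(z, tau2), rel=1e-8)
        assert quadrature_bf10(TestReport("z", z, n=50), prior) == pytest.approx(
            simpson_bf, rel=1e-8
        )

    def test_mismatched_prior_family_rejected(self):
        with pytest.raises(TypeError):
            quadrature_bf10(TestReport("z", 1.0, n=50), GammaNCPrior(1, 1.0))
        with pytest.raises(TypeError):
            quadrature_bf10(
                TestReport("chisq", 1.0, df1=2, n=50), NormalMomentPrior(0.0, 1.0)
            )


class TestDispatch:
    def test_dispatch_matches_direct_calls(self):
        pairs = [
            (TestReport("z", 2.0, n=100), bf10_z(2.0, 1.125)),
            (TestReport("t", 2.2, n=31, df2=30), bf10_t(2.2, 30, 1.125)),
            (TestReport("chisq", 12.65, df1=6, n=707), bf10_chisq(12.65, 6, 1.125)),
            (TestReport("f", 4.05, df1=2, df2=82, n=85), bf10_f(4.05, 2, 82, 1.125)),
        ]
        for rep, direct in pairs:
            assert bf10(rep, 1.125) == direct

    def test_report_validation(self):
        with pytest.raises(ValueError):
            TestReport("g", 1.0, n=10)
        with pytest.raises(ValueError):
            TestReport("t", 1.0, n=10)  # missing df2
        with pytest.raises(ValueError):
            TestReport("chisq", -1.0, df1=2, n=10)
        with pytest.raises(ValueError):
            TestReport("f", 1.0, df1=2, df2=30, n=10, design="one_sample")
        with pytest.raises(ValueError):
            TestReport("z", 1.0, n=(10, 10), design="one_sample")


class TestPosteriorOdds:
    def test_even_prior_odds_pass_through(self):
        assert posterior_odds(2.90, 1.0) == pytest.approx(2.90)

    def test_reciprocal_prior_odds_neutralize(self):
        assert posterior_odds(3.5, 1 / 3.5) == pytest.approx(1.0)

    def test_product(self):
        assert posterior_odds(3.07, 0.5) == pytest.approx(1.535)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            posterior_odds(0.0, 1.0)
        with pytest.raises(ValueError):
            posterior_odds(1.0, -2.0)


class TestLikelihoodRatioCurve:
    def test_zero_effect_gives_unit_ratio(self):
        for rep in [
            TestReport("z", 2.0, n=100),
            TestReport("chisq", 12.65, df1=6, n=707),
            TestReport("f", 4.05, df1=2, df2=82, n=85),
        ]:
            [(_, ratio)] = likelihood_ratio_curve(rep, [1e-12])
            assert ratio == pytest.approx(1.0, abs=1e-6)

    def test_z_family_closed_form(self, z_report):
        # ratio(omega) = exp(z*sqrt(n)*omega - n*omega^2/2)
        omegas = [0.05, 0.15, 0.3]
        curve = likelihood_ratio_curve(z_report, omegas)
        for w, ratio in curve:
            lam = math.sqrt(100) * w
            assert ratio == pytest.approx(math.exp(2.0 * lam - lam**2 / 2), rel=1e-10)

    def test_peak_dominates_prior_averaged_maximum(self, z_report):
        grid = np.arange(0.01, 1.0, 0.005)
        lr = max(r for _, r in likelihood_ratio_curve(z_report, grid))
        res = bff.BayesFactorFunction(z_report).fit()
        assert lr >= res.max_bf10
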