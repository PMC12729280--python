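import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from growthkin.errors import DegenerateStitchError, DomainError
from growthkin.models import (
    BaranyiParams,
    GompertzParams,
    HybridParams,
    LogisticLagParams,
    LogisticParams,
    MODEL_REGISTRY,
    MonodGaussParams,
    baranyi_roberts,
    get_model,
    gompertz,
    hybrid_two_phase,
    logistic,
    logistic_lag,
    logistic_ode_rhs,
    monod_gauss,
)

LOG = LogisticParams(X0=0.33, K=4.5, mu=0.03)


class TestLogistic:
    def test_t0_is_x0(self):
        assert logistic(0.0, LOG) == pytest.approx(0.33)

    def test_asymptote(self):
        assert logistic(1e6, LOG) == pytest.approx(4.5, abs=1e-9)

    def test_half_capacity_at_inflection(self):
        # closed-form inflection: t* = ln((K - X0)/X0)/mu
        t_star = np.log((LOG.K - LOG.X0) / LOG.X0) / LOG.mu
        assert logistic(t_star, LOG) == pytest.approx(LOG.K / 2, rel=1e-12)
        # cross-check by numerical root finding on X(t) - K/2
        from scipy.optimize import brentq

        root = brentq(lambda t: float(logistic(t, LOG)) - LOG.K / 2, 0, 700)
        assert root == pytest.approx(t_star, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            LogisticParams(X0=0.0, K=4.5, mu=0.03)
        with pytest.raises(DomainError):
            LogisticParams(X0=0.33, K=0.0, mu=0.03)

    def test_strictly_increasing(self):
        t = np.linspace(0, 700, 500)
        x = logistic(t, LOG)
        assert np.all(np.diff(x) > 0)

    @given(
        x0=st.floats(0.01, 2.0),
        k_extra=st.floats(0.1, 10.0),
        mu=st.floats(1e-4, 0.5),
    )
    @settings(max_examples=30, deadline=None)
    def test_matches_ode_integration(self, x0, k_extra, mu):
        p = LogisticParams(X0=x0, K=x0 + k_extra, mu=mu)
        t_eval = np.linspace(0, 700, 40)
        sol = solve_ivp(
            lambda t, x: logistic_ode_rhs(x, p),
            (0, 700),
            [p.X0],
            t_eval=t_eval,
            rtol=1e-10,
            atol=1e-12,
            method="LSODA",
        )
        np.testing.assert_allclose(logistic(t_eval, p), sol.y[0], rtol=1e-6)


class TestLogisticLag:
    P = LogisticLagParams(X0=0.33, K=4.5, mu=0.03, t_lag=48.0)

    def test_constant_before_lag(self):
        t = np.array([0.0, 10.0, 47.9])
        np.testing.assert_array_equal(logistic_lag(t, self.P), 0.33)

    def test_zero_lag_reduces_to_logistic(self):
        p0 = LogisticLagParams(X0=0.33, K=4.5, mu=0.03, t_lag=0.0)
        t = np.linspace(0, 700, 100)
        np.testing.assert_array_equal(logistic_lag(t, p0), logistic(t, LOG))

    def test_continuity_at_lag(self):
        assert logistic_lag(self.P.t_lag, self.P) == pytest.approx(0.33)
        assert logistic_lag(self.P.t_lag + 1e-9, self.P) == pytest.approx(0.33, abs=1e-9)

    def test_negative_lag_rejected(self):
        with pytest.raises(DomainError):
            LogisticLagParams(X0=0.33, K=4.5, mu=0.03, t_lag=-1.0)


class TestGompertz:
    P = GompertzParams(Xmax=4.5, mumax=0.012, lam=50.0)

    def test_asymptote(self):
        assert gompertz(1e6, self.P) == pytest.approx(4.5, abs=1e-9)

    def test_value_at_lambda(self):
        # the double-exponent reduces to exp(-e) at t = lam
        assert gompertz(self.P.lam, self.P) == pytest.approx(
            self.P.Xmax * np.exp(-np.e), rel=1e-12
        )
        assert gompertz(self.P.lam, self.P) == pytest.approx(
            0.0659880 * self.P.Xmax, rel=1e-5
        )

    def test_max_slope_equals_mumax(self):
        # numerical differentiation oracle on a fine grid
        t = np.linspace(0, 1500, 300001)
        x = gompertz(t, self.P)
        slope_max = np.max(np.gradient(x, t))
        assert slope_max == pytest.approx(self.P.mumax, rel=1e-4)

    def test_monotone_and_bounded(self):
        t = np.linspace(0, 700, 1000)
        x = gompertz(t, self.P)
        assert np.all(np.diff(x) >= 0)
        assert np.all(x <= self.P.Xmax)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            GompertzParams(Xmax=0.0, mumax=0.01, lam=0.0)


class TestBaranyiRoberts:
    P = BaranyiParams(mumax=0.05, lam=50.0, C=2.6, X0=0.33)

    def test_t0_is_x0(self):
        assert baranyi_roberts(0.0, self.P) == pytest.approx(0.33, rel=1e-12)

    def test_asymptote_x0_exp_c(self):
        expected = self.P.X0 * np.exp(self.P.C)
        assert baranyi_roberts(1e6, self.P) == pytest.approx(expected, rel=1e-6)

    def test_zero_lag_closed_form(self):
        # direct hand-substituted lambda=0 expression as oracle
        p = BaranyiParams(mumax=0.05, lam=0.0, C=2.6, X0=0.33)
        t = np.linspace(0, 300, 50)
        u = p.mumax * t
        y = u - np.log(1 + (np.exp(u) - 1) / np.exp(p.C))
        np.testing.assert_allclose(
            baranyi_roberts(t, p), p.X0 * np.exp(y), rtol=1e-9
        )

    def test_stable_at_large_rate_time(self):
        p = BaranyiParams(mumax=1.0, lam=10.0, C=2.6, X0=0.33)
        x = baranyi_roberts(np.array([0.0, 350.0, 700.0]), p)
        assert np.all(np.isfinite(x))
        assert x[-1] == pytest.approx(p.X0 * np.exp(p.C), rel=1e-9)

    def test_zero_mumax_limit(self):
        p = BaranyiParams(mumax=0.0, lam=50.0, C=2.6, X0=0.33)
        np.testing.assert_array_equal(
            baranyi_roberts(np.array([0.0, 100.0]), p), 0.33
        )

    def test_negative_c_rejected(self):
        with pytest.raises(DomainError):
            BaranyiParams(mumax=0.05, lam=0.0, C=-1.0, X0=0.33)


class TestHybridTwoPhase:
    P = HybridParams(X0=0.33, a=0.01, t_s=300.0, K=4.4, r=0.02)

    def test_t0_is_x0(self):
        assert hybrid_two_phase(0.0, self.P) == pytest.approx(0.33)

    def test_continuity_at_stitch(self):
        left = self.P.X0 + self.P.a * self.P.t_s
        # both branches agree to machine precision at the stitch
        assert hybrid_two_phase(self.P.t_s, self.P) == pytest.approx(left, rel=1e-13)
        assert hybrid_two_phase(self.P.t_s - 1e-12, self.P) == pytest.approx(left)

    def test_asymptote(self):
        assert hybrid_two_phase(1e6, self.P) == pytest.approx(self.P.K, abs=1e-9)

    def test_degenerate_stitch(self):
        with pytest.raises(DegenerateStitchError):
            HybridParams(X0=0.33, a=0.01, t_s=500.0, K=4.0, r=0.02)

    @given(
        x0=st.floats(0.05, 1.0),
        a=st.floats(0.0, 0.02),
        t_s=st.floats(0.0, 400.0),
        k_extra=st.floats(0.01, 5.0),
        r=st.floats(0.0, 0.1),
    )
    @settings(max_examples=50, deadline=None)
    def test_exact_continuity_property(self, x0, a, t_s, k_extra, r):
        p = HybridParams(X0=x0, a=a, t_s=t_s, K=x0 + a * t_s + k_extra, r=r)
        stitch = p.X0 + p.a * p.t_s
        both = hybrid_two_phase(np.array([t_s - 1e-12, t_s]), p)
        assert both[1] == pytest.approx(stitch, rel=1e-13)  # logistic branch
        assert both[0] == pytest.approx(stitch, rel=1e-9)  # linear branch

    def test_monotone_when_valid(self):
        t = np.linspace(0, 700, 1000)
        x = hybrid_two_phase(t, self.P)
        assert np.all(np.diff(x) >= 0)


class TestMonodGauss:
    P = MonodGaussParams(mumax=0.0136, KB=0.5, Topt=26.0, sigma=3.3)

    def test_supremum_at_topt_large_b(self):
        assert monod_gauss(26.0, 1e9, self.P) == pytest.approx(0.0136, rel=1e-6)

    def test_half_saturation(self):
        assert monod_gauss(26.0, 0.5, self.P) == pytest.approx(0.0136 / 2)

    def test_reported_fit_value(self):
        # mumax/2 at (Topt, KB) for the reported parameter values
        assert monod_gauss(26.0, 0.5, self.P) == pytest.approx(0.0068)

    def test_symmetry_in_temperature(self):
        # dyadic offsets keep 26 +/- d exact in binary floating point
        d = np.arange(0, 10.25, 0.25)
        np.testing.assert_array_equal(
            monod_gauss(26.0 + d, 1.0, self.P), monod_gauss(26.0 - d, 1.0, self.P)
        )

    def test_increasing_in_aeration(self):
        b = np.linspace(0, 5, 200)
        mu = monod_gauss(26.0, b, self.P)
        assert np.all(np.diff(mu) > 0)

    def test_bounded_by_mumax(self):
        b = np.linspace(0, 100, 50)
        T = np.full_like(b, 26.0)
        mu = monod_gauss(T, b, self.P)
        assert np.all((0 <= mu) & (mu < self.P.mumax))

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            MonodGaussParams(mumax=0.0136, KB=0.0, Topt=26, sigma=3.3)
        with pytest.raises(DomainError):
            MonodGaussParams(mumax=0.0136, KB=0.5, Topt=26, sigma=0.0)
        with pytest.raises(DomainError):
            monod_gauss(26.0, -1.0, self.P)


class TestLogisticOdeRhs:
    def test_fixed_points(self):
        assert logistic_ode_rhs(0.0, LOG) == 0.0
        assert logistic_ode_rhs(LOG.K, LOG) == pytest.approx(0.0)

    def test_max_rate_at_half_capacity(self):
        # vertex of the quadratic, verified by grid search
        assert logistic_ode_rhs(LOG.K / 2, LOG) == pytest.approx(
            LOG.mu * LOG.K / 4
        )
        grid = np.linspace(0, LOG.K, 10001)
        rates = logistic_ode_rhs(grid, LOG)
        assert grid[np.argmax(rates)] == pytest.approx(LOG.K / 2, rel=1e-3)


class TestRegistry:
    def test_canonical_names(self):
        assert set(MODEL_REGISTRY) == {
            "logistic",
            "logistic_lag",
            "gompertz",
            "baranyi_roberts",
            "hybrid_two_phase",
        }

    def test_unknown_model(self):
        with pytest.raises(KeyError):
            get_model("exponential")

    def test_param_names_match_units(self):
        for spec in MODEL_REGISTRY.values():
            assert len(spec.param_names) == len(spec.units)

    @pytest.mark.parametrize("name", sorted(MODEL_REGISTRY))
    def test_finite_nonnegative_over_campaign_horizon(self, name):
        # no overflow even at rate 1/h over 700 h
        values = {
            "logistic": {"X0": 0.33, "K": 4.5, "mu": 1.0},
            "logistic_lag": {"X0": 0.33, "K": 4.5, "mu": 1.0, "t_lag": 100.0},
            "gompertz": {"Xmax": 4.5, "mumax": 1.0, "lam": 100.0},
            "baranyi_roberts": {"mumax": 1.0, "lam": 100.0, "C": 2.6, "X0": 0.33},
            "hybrid_two_phase": {"X0": 0.33, "a": 0.005, "t_s": 300.0, "K": 4.4,
                                 "r": 1.0},
        }[name]
        t = np.linspace(0, 700, 2000)
        x = MODEL_REGISTRY[name].predict_named(t, values)
        assert np.all(np.isfinite(x))
        assert np.all(x >= 0)
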