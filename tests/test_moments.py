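"""Exact moment engine, closed-form special cases and small-weight formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aoncb import (
    BetaBinomialModel,
    CorrelationSpec,
    DiscreteJumpModel,
    InputPool,
    NeuronParams,
    correlation_shared_inputs,
    correlation_synchrony,
    covariance_small_weight,
    excitatory_variability_share,
    general_mixed_moment,
    heterogeneity_equivalent_variance,
    kappa_synchrony,
    moment_table,
    skewness_excitation_approx,
    skewness_sign_change_rate,
    small_weight_mean,
    stationary_covariance,
    stationary_mean,
    third_moment,
    variance_asynchronous,
    variance_small_weight,
)

from conftest import random_discrete_model


class TestStationaryMean:
    def test_vanishing_drive_relaxes_to_leak(self, params):
        jm = DiscreteJumpModel(labels=(0,), rate=1e-9, We=np.array([[0.1]]),
                               Wi=np.array([[0.0]]), probs=np.array([1.0]))
        assert stationary_mean(jm, params) == pytest.approx(0.0, abs=1e-6)

    def test_excitatory_saturation(self, params):
        jm = DiscreteJumpModel(labels=(0,), rate=1e6, We=np.array([[5.0]]),
                               Wi=np.array([[0.0]]), probs=np.array([1.0]))
        assert stationary_mean(jm, params) == pytest.approx(params.Ve, rel=1e-3)

    def test_small_weight_worked_value(self, params):
        # Ke re we = 10 Hz, Ki ri wi = 1 Hz -> m = 590/77.67 mV
        pools = [InputPool("e", 10**5, 1e-4, 1.0), InputPool("i", 10**4, 1e-4, 1.0)]
        m_sw = small_weight_mean(pools, params)
        assert m_sw == pytest.approx(590.0 / (200.0 / 3.0 + 11.0), rel=1e-9)
        jm = DiscreteJumpModel.from_asynchronous_pools(pools)
        assert stationary_mean(jm, params) == pytest.approx(m_sw, rel=1e-3)

    def test_bounded_by_reversals(self, params, rng):
        for _ in range(10):
            jm = random_discrete_model(rng)
            m = stationary_mean(jm, params)
            assert params.Vi < m < params.Ve


class TestStationaryCovariance:
    def test_independent_drives_are_uncorrelated(self, params):
        We = np.array([[0.2, 0.0], [0.0, 0.3]])
        jm = DiscreteJumpModel(labels=(1, 2), rate=800.0, We=We,
                               Wi=np.zeros((2, 2)), probs=np.array([0.4, 0.6]))
        assert stationary_covariance(jm, params, labels=(1, 2)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_variance_recovered_for_identical_labels(self, params):
        pools = [InputPool("e", 30, 0.02, 10.0), InputPool("i", 10, 0.05, 8.0)]
        jm = DiscreteJumpModel.from_asynchronous_pools(pools)
        var_closed = variance_asynchronous(pools, params)
        var_engine = stationary_covariance(jm, params, labels=(0, 0))
        assert var_engine == pytest.approx(var_closed, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_cauchy_schwarz(self, seed):
        rng = np.random.default_rng(seed)
        jm = random_discrete_model(rng, n_neurons=2)
        p = NeuronParams()
        c12 = stationary_covariance(jm, p, labels=(0, 1))
        v1 = stationary_covariance(jm, p, labels=(0, 0))
        v2 = stationary_covariance(jm, p, labels=(1, 1))
        assert abs(c12) <= math.sqrt(v1 * v2) * (1 + 1e-9)


class TestGeneralMixedMoment:
    def test_order_one_equals_mean(self, params, rng):
        jm = random_discrete_model(rng)
        mu1 = general_mixed_moment(jm, params, [0])
        assert mu1 + params.Iratio == pytest.approx(stationary_mean(jm, params))

    def test_order_two_pair_consistency(self, params, rng):
        jm = random_discrete_model(rng, n_neurons=2)
        mu = general_mixed_moment(jm, params, [0, 1])
        m1 = stationary_mean(jm, params, 0)
        m2 = stationary_mean(jm, params, 1)
        cov = stationary_covariance(jm, params, labels=(0, 1))
        assert mu == pytest.approx(cov + m1 * m2, rel=1e-10)

    def test_nonzero_resting_current_consistency(self, rng):
        p = NeuronParams(Iratio=3.0)
        jm = random_discrete_model(rng)
        tab = moment_table(jm, p, order=2)
        assert tab.means[0] == pytest.approx(stationary_mean(jm, p), rel=1e-12)
        assert tab.variance(0) >= 0

    def test_centered_shifted_consistency(self, params, rng):
        jm = random_discrete_model(rng)
        tab = moment_table(jm, params, order=3)
        mu1 = tab.shifted[(0,)]
        mu2 = tab.shifted[(0, 0)]
        mu3 = tab.shifted[(0, 0, 0)]
        assert tab.centered[(0, 0)] == pytest.approx(mu2 - mu1**2, rel=1e-12)
        assert tab.centered[(0, 0, 0)] == pytest.approx(
            mu3 - 3 * mu2 * mu1 + 2 * mu1**3, rel=1e-10
        )

    def test_higher_order_even_moment_positive(self, params, rng):
        jm = random_discrete_model(rng)
        tab = moment_table(jm, params, order=4)
        assert tab.centered[(0, 0, 0, 0)] > 0


class TestThirdMoment:
    def test_symmetric_drive_has_zero_skew(self):
        p = NeuronParams(Ve=30.0, Vi=-30.0)
        # exchange-symmetric e/i statistics around VL = 0
        We = np.array([[0.2, ], [0.0, ]])
        Wi = np.array([[0.0, ], [0.2, ]])
        jm = DiscreteJumpModel(labels=(0,), rate=1000.0, We=We, Wi=Wi,
                               probs=np.array([0.5, 0.5]))
        M3, skew = third_moment(jm, p)
        assert stationary_mean(jm, p) == pytest.approx(0.0, abs=1e-12)
        assert M3 == pytest.approx(0.0, abs=1e-10)

    def test_compact_closed_form_equals_engine(self, params, rng):
        # M3 = b (E[R^3(1-Y)^3] + 3 M2 E[R (Y^2-1)(1-Y)]) / (3/tau + b E[1-Y^3])
        jm = random_discrete_model(rng)
        m = stationary_mean(jm, params)
        M2 = stationary_covariance(jm, params, labels=(0, 0))
        W = jm.We[:, 0] + jm.Wi[:, 0]
        Y = np.exp(-W)
        safe = np.where(W > 0, W, 1.0)
        R = np.where(W > 0, (jm.We[:, 0] * params.Ve + jm.Wi[:, 0] * params.Vi) / safe - m, 0.0)
        E = lambda f: float(np.sum(jm.probs * f))
        closed = jm.rate * (
            E(R**3 * (1 - Y) ** 3) + 3 * M2 * E(R * (Y**2 - 1) * (1 - Y))
        ) / (3 / params.tau + jm.rate * E(1 - Y**3))
        M3, _ = third_moment(jm, params)
        assert M3 == pytest.approx(closed, rel=1e-10)

    def test_zero_variance_skewness_rejected(self):
        from aoncb import MomentTable

        tab = MomentTable(labels=(0,))
        tab.centered[(0, 0)] = 0.0
        tab.centered[(0, 0, 0)] = 0.0
        with pytest.raises(ZeroDivisionError):
            tab.skewness(0)


class TestVarianceFormulas:
    def test_asynchronous_zero_weights(self, params):
        pools = [InputPool("e", 10, 0.0, 5.0)]
        assert variance_asynchronous(pools, params) == 0.0

    def test_asynchronous_matches_engine(self, params):
        pools = [InputPool("e", 50, 0.01, 10.0), InputPool("i", 12, 0.04, 7.0)]
        jm = DiscreteJumpModel.from_asynchronous_pools(pools)
        assert variance_asynchronous(pools, params) == pytest.approx(
            stationary_covariance(jm, params, labels=(0, 0)), rel=1e-12
        )

    def test_small_weight_limit_of_asynchronous(self, params):
        pools = [InputPool("e", 10**4, 1e-4, 10.0)]
        exact = variance_asynchronous(pools, params)
        approx = variance_small_weight(pools, None, params)
        assert approx == pytest.approx(exact, rel=5e-4)

    def test_synchrony_amplification_factor(self, params):
        # Ke=1000, rho=0.01: variance ratio sync/async = 1 + (K-1) rho
        K, rho, w, r = 1000, 0.01, 1e-3, 10.0
        pools = [InputPool("e", K, w, r)]
        v0 = variance_small_weight(pools, None, params)
        v1 = variance_small_weight(
            pools, CorrelationSpec(block_rho=np.array([[rho]])), params
        )
        assert v1 / v0 == pytest.approx(1 + (K - 1) * rho, rel=1e-9)

    def test_variance_monotone_in_within_pool_rho(self, params):
        pools = [InputPool("e", 500, 1e-3, 10.0), InputPool("i", 125, 4e-3, 10.0)]
        vals = [
            variance_small_weight(
                pools,
                CorrelationSpec(block_rho=np.array([[rho, 1e-15], [1e-15, rho]])),
                params,
            )
            for rho in (0.005, 0.01, 0.02, 0.04)
        ]
        assert all(np.diff(vals) > 0)

    def test_ei_synchrony_reduces_variance(self, params):
        pools = [InputPool("e", 500, 1e-3, 10.0), InputPool("i", 125, 4e-3, 10.0)]
        base = variance_small_weight(
            pools, CorrelationSpec(block_rho=np.array([[0.03, 1e-15], [1e-15, 0.03]])),
            params,
        )
        mixed = variance_small_weight(
            pools, CorrelationSpec(block_rho=np.array([[0.03, 0.02], [0.02, 0.03]])),
            params,
        )
        assert mixed < base


class TestCovarianceSmallWeight:
    def test_uncorrelated_pair_has_zero_covariance(self, params):
        pools = [InputPool("e", 100, 1e-3, 10.0)]
        assert covariance_small_weight(pools, pools, [], params) == 0.0

    def test_pure_ei_cross_correlation_is_negative(self, params):
        pools = [InputPool("e", 100, 1e-3, 10.0), InputPool("i", 25, 4e-3, 10.0)]
        cov = covariance_small_weight(
            pools, pools, [(0, 1, 0.02), (1, 0, 0.02)], params
        )
        assert cov < 0

    def test_matches_exact_engine_on_small_weight_pair(self, params):
        # two neurons, each driven by its own input plus a shared one
        w = 2e-3
        We = np.array([[w, 0.0], [0.0, w], [w, w]])
        jm = DiscreteJumpModel(labels=(1, 2), rate=3000.0, We=We,
                               Wi=np.zeros((3, 2)), probs=np.array([0.4, 0.4, 0.2]))
        exact = stationary_covariance(jm, params, labels=(1, 2))
        # equivalent per-neuron pools: rate r = b * P(atom) per input
        shared_r = 3000.0 * 0.2
        own_r = 3000.0 * 0.4
        pools1 = [InputPool("e", 1, w, own_r), InputPool("e", 1, w, shared_r)]
        pools2 = [InputPool("e", 1, w, own_r), InputPool("e", 1, w, shared_r)]
        approx = covariance_small_weight(
            pools1, pools2, [(1, 1, 1.0, 1)], params
        )
        assert approx == pytest.approx(exact, rel=5 * w)


class TestWorkedShareAndKappa:
    def test_share_at_rest_is_90_percent(self, params):
        q = excitatory_variability_share(10**4, 10.0, 1e-4, 2500, 10.0, 4e-4, 0.0, params)
        assert q == pytest.approx(0.9, abs=1e-12)

    def test_share_declines_with_depolarization(self, params):
        q15 = excitatory_variability_share(10**4, 10.0, 1e-4, 2500, 10.0, 4e-4, 15.0, params)
        assert q15 == pytest.approx(0.4475, abs=5e-4)

    def test_share_without_inhibition_is_one(self, params):
        assert excitatory_variability_share(100, 10.0, 0.01, 0, 10.0, 0.04, 5.0, params) == 1.0

    def test_kappa_case_i(self):
        assert kappa_synchrony(100, 25, 0.8, "i") == pytest.approx(85.0)

    def test_kappa_case_ii_cancellation(self):
        # cross-correlated e-i: sqrt cancellation of driving forces
        val = kappa_synchrony(10**4, 2500, 0.9, "ii")
        assert val == pytest.approx((math.sqrt(9000) - math.sqrt(250)) ** 2)
        assert val / 10**4 == pytest.approx(0.625, abs=1e-9)


class TestVoltageCorrelationFormulas:
    def test_shared_inputs_worked_values(self):
        assert correlation_shared_inputs(1.0, 1.0, 0.3) == 1.0
        assert correlation_shared_inputs(1.0, 0.0, 0.9) == pytest.approx(0.9)
        assert correlation_shared_inputs(0.85, 0.40, 0.45) == pytest.approx(0.6025)

    def test_synchrony_saturation_limit(self):
        assert correlation_synchrony(0.03, 0.03, 1e12) == pytest.approx(1.0)

    def test_excitation_alone_linear_regime(self):
        # kappa = Ke, small Ke*rho: rho_V ~ rho' * Ke
        rho, rho_c, Ke = 0.02, 0.01, 5
        val = correlation_synchrony(rho, rho_c, float(Ke))
        assert val == pytest.approx(rho_c * Ke, rel=0.15)

    @given(
        st.floats(0.01, 0.99), st.floats(0.0, 1.0), st.floats(0.5, 1e6)
    )
    @settings(max_examples=100, deadline=None)
    def test_upper_bound_rho_ratio(self, rho, frac, kappa):
        rho_c = rho * frac
        val = correlation_synchrony(rho, rho_c, kappa)
        assert val <= rho_c / rho + 1e-12
        assert 0 <= val <= 1.0 + 1e-12

    def test_inadmissible_cross_correlation_rejected(self):
        with pytest.raises(ValueError):
            correlation_synchrony(0.02, 0.03, 10.0)


class TestSkewnessApprox:
    def test_sign_change_at_half_inverse_tau(self, params):
        rate = skewness_sign_change_rate(params.tau)
        assert rate == pytest.approx(1.0 / (2 * params.tau), rel=1e-9)
        out = skewness_excitation_approx(1000, 1e-3, rate, 0.02, params)
        assert out["skewness"] == pytest.approx(0.0, abs=1e-9)

    def test_synchrony_amplifies_right_skew(self, params):
        s0 = skewness_excitation_approx(1000, 1e-3, 1.0, 0.0, params)["skewness"]
        s1 = skewness_excitation_approx(1000, 1e-3, 1.0, 0.03, params)["skewness"]
        assert s1 > s0 > 0
        assert s1 / s0 == pytest.approx(math.sqrt(1 + 0.03 * 1000), rel=1e-12)

    def test_baseline_scales_inverse_sqrt_drive(self, params):
        b1 = skewness_excitation_approx(1000, 1e-3, 1.0, 0.0, params)
        b25 = skewness_excitation_approx(1000, 1e-3, 25.0, 0.0, params)
        ratio = b1["current_based_baseline"] / b25["current_based_baseline"]
        assert ratio == pytest.approx(5.0, rel=1e-12)


class TestHeterogeneity:
    def test_equal_weights_no_amplification(self, params):
        out = heterogeneity_equivalent_variance([1e-3] * 50, 10.0, params)
        assert out["cv2"] == pytest.approx(0.0, abs=1e-15)
        assert out["amplification"] == pytest.approx(1.0)

    def test_two_point_weights_worked_value(self, params):
        # weights {w, 3w} equally: CV^2 = 1/4
        out = heterogeneity_equivalent_variance([1e-3, 3e-3] * 25, 10.0, params)
        assert out["cv2"] == pytest.approx(0.25, rel=1e-12)
        assert out["amplification"] == pytest.approx(1.25)

    def test_unit_cv_doubles_variance(self, params):
        rng = np.random.default_rng(0)
        w = rng.exponential(1e-3, 4000)  # CV = 1 in expectation
        out = heterogeneity_equivalent_variance(w, 10.0, params)
        assert out["amplification"] == pytest.approx(2.0, rel=0.1)

    def test_identity_against_variance_formula(self, params):
        w = [1e-3, 2e-3, 5e-4, 3e-3]
        out = heterogeneity_equivalent_variance(w, 10.0, params)
        pool = InputPool("e", len(w), w, 10.0)
        assert out["variance"] == pytest.approx(
            variance_small_weight([pool], None, params), rel=1e-12
        )
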