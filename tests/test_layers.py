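"""Layer solutions, matching closure and the composite construction."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from drylandwaves import DomainError
from drylandwaves.layers import (EULER_GAMMA, compose, composite_deviation,
                                 exp_integral, layer1_eval,
                                 layer1_farfield_W, layer2_eval,
                                 layer3_correction, layer3_leading,
                                 matching_constants, peak_adapted_k7)


class TestExpIntegral:
    def test_small_argument_expansion(self):
        for xi in (1e-10, 1e-8, 1e-6):
            assert exp_integral(xi) + math.log(xi) + EULER_GAMMA == \
                pytest.approx(0.0, abs=2 * xi)

    def test_derivative_is_minus_integrand(self):
        xi = 0.8
        h = 1e-6
        fd = (exp_integral(xi + h) - exp_integral(xi - h)) / (2 * h)
        assert fd == pytest.approx(-math.exp(-xi) / xi, rel=1e-6)

    def test_value_against_quadrature(self):
        val, _ = quad(lambda t: math.exp(-t) / t, 1.0, 200.0)
        assert exp_integral(1.0) == pytest.approx(val, rel=1e-9)

    def test_domain(self):
        with pytest.raises(DomainError):
            exp_integral(0.0)


class TestLayer2:
    def test_uptake_balances_rainfall_identically(self, constants):
        z2 = np.linspace(-8, 0, 300)
        W2, U2, J2, M2 = layer2_eval(z2, constants)
        p = constants.params
        assert np.allclose(U2 * U2 * W2, p.a, rtol=1e-14)

    def test_exponential_growth_rate(self, constants):
        z2 = np.linspace(-3, 0, 50)
        _, U2, _, _ = layer2_eval(z2, constants)
        dU = np.gradient(U2, z2)
        assert np.allclose(dU[1:-1], constants.alpha * U2[1:-1], rtol=1e-3)

    def test_junction_values(self, constants):
        W2, U2, J2, M2 = layer2_eval(0.0, constants)
        k, p = constants, constants.params
        assert W2 == pytest.approx(p.a / k.k1 ** 2)
        assert U2 == pytest.approx(k.k1)
        assert J2 == pytest.approx(k.k2)
        assert M2 == pytest.approx(k.k3 - p.eta ** 2 * k.k1 / k.alpha)


class TestLayer1:
    def test_boundary_values(self, constants):
        W1, U1, J1, M1 = layer1_eval(0.0, constants)
        k = constants
        assert U1 == pytest.approx(k.k10)
        assert J1 == pytest.approx(k.k11)
        assert M1 == pytest.approx(k.k3)

    def test_water_equation_residual(self, constants):
        # nu W1' = U1^2 W1 - a along the layer
        p = constants.params
        z1 = np.linspace(-2.0, 0.0, 2001)
        W1, U1, _, _ = layer1_eval(z1, constants)
        dW1 = np.gradient(W1, z1)
        resid = p.nu * dW1 - (U1 * U1 * W1 - p.a)
        assert np.abs(resid[1:-1]).max() < 1e-3 * np.abs(W1).max() * p.nu

    def test_far_field_is_linear_water_ramp(self, constants):
        p = constants.params
        z1 = np.array([-40.0, -60.0])
        W1, _, _, _ = layer1_eval(z1, constants)
        ff = layer1_farfield_W(z1, constants)
        assert W1 == pytest.approx(ff, rel=1e-10)
        slope = (ff[1] - ff[0]) / (z1[1] - z1[0])
        assert slope == pytest.approx(-p.a / p.nu, rel=1e-12)


class TestLayer3:
    def test_conservation_law(self, constants):
        p = constants.params
        z3 = np.linspace(-50, 5000, 200)
        W3, U3 = layer3_leading(z3, constants)
        assert np.allclose(p.nu * W3 + U3, constants.k6, rtol=1e-12)

    def test_asymptotic_limits(self, constants):
        p = constants.params
        _, U_left = layer3_leading(np.array([-1e7]), constants)
        assert U_left[0] == pytest.approx(constants.k6, rel=1e-6)
        z3 = 1e7
        _, U_right = layer3_leading(np.array([z3]), constants)
        assert U_right[0] == pytest.approx(p.nu / (constants.k6 * z3),
                                           rel=1e-2)

    def test_profile_monotone_decreasing(self, constants):
        z3 = np.linspace(-20, 200, 500)
        _, U3 = layer3_leading(z3, constants)
        assert np.all(np.diff(U3) < 0)


class TestLayer3Correction:
    def test_first_order_system_residual(self, constants):
        # the recovered (U3_0, W3_1) satisfy dU3_0/du = u^2 g(u) + 2 U3_0/u
        k, p = constants, constants.params
        u = np.linspace(0.2 * k.k6, 0.8 * k.k6, 400)
        U30, W31 = layer3_correction(u, k)
        # residual of the pair against the coupled first-order equations:
        # dU3_0/dU3^-1 = -alpha/(u W3_0) + W3_1/W3_0 + 2 U3_0/u
        W30 = (k.k6 - u) / p.nu
        dU30 = np.gradient(U30, u)
        rhs = -k.alpha / (u * W30) + W31 / W30 + 2 * U30 / u
        mid = slice(5, -5)
        scale = np.abs(rhs[mid]).max()
        assert np.abs(dU30[mid] - rhs[mid]).max() < 1e-2 * scale

    def test_outer_matching_limit_gauge_independent(self, constants):
        p = constants.params
        lim = p.alpha * p.nu / (2 * constants.k6)
        for k8 in (-1.0, 0.0, 1.0):
            U30, _ = layer3_correction(
                np.array([1e-6 * constants.k6]),
                constants.with_gauges(k8=k8))
            assert U30[0] == pytest.approx(lim, rel=1e-3)

    def test_grid_must_be_monotone(self, constants):
        with pytest.raises(Exception):
            layer3_correction(np.array([1.0, 0.5, 2.0]), constants)


class TestMatching:
    def test_closure_relations(self, constants, outer_ref):
        k, p = constants, constants.params
        assert k.k1 == k.k6 == pytest.approx(p.nu * outer_ref.W0)
        assert k.k11 == k.k2 == k.k4 == pytest.approx(outer_ref.J0)
        assert k.k3 == pytest.approx(outer_ref.M_L)
        assert k.k5 == pytest.approx(outer_ref.M0)
        assert k.k5 == pytest.approx(k.k3 - p.eta ** 2 * k.k1 / k.alpha,
                                     abs=1e-6)
        assert k.W0 * k.J0 == pytest.approx(k.alpha ** 2 / (4 * p.d),
                                            abs=1e-8)
        assert k.U0 == pytest.approx(k.alpha * p.nu / (2 * k.k6))

    def test_beta_gauge_moves_k10(self, outer_ref):
        k0 = matching_constants(outer_ref, beta=0.0)
        kb = matching_constants(outer_ref, beta=0.5)
        assert k0.k10 == pytest.approx(k0.k6)
        assert kb.k10 == pytest.approx(k0.k6 * math.exp(k0.alpha * 0.5))

    def test_layer12_water_matching_identity(self, constants):
        # c W1(0) must equal c^2 W2(z2*) by construction of k9
        k, p = constants, constants.params
        c = 1e-3
        W1_0 = layer1_eval(0.0, k)[0]
        z2_star = math.log(c) / (2 * k.alpha) + k.beta
        W2_star = layer2_eval(z2_star, k)[0]
        assert c * W1_0 == pytest.approx(c * c * W2_star, rel=1e-10)


class TestComposite:
    def test_period_identity(self, outer_ref, constants):
        for c in (1e-2, 1e-3):
            comp = compose(outer_ref, constants, c=c)
            expected = outer_ref.L - c * math.log(c) / (2 * constants.alpha)
            assert comp.L_comp == expected

    def test_plant_density_positive(self, outer_ref, constants):
        comp = compose(outer_ref, constants, c=1e-3)
        assert comp.U.min() > 0

    def test_gauge_invariance_in_beta(self, outer_ref, wave_c1e3):
        k0 = matching_constants(outer_ref, beta=0.0)
        kb = matching_constants(outer_ref, beta=0.5)
        d0 = composite_deviation(compose(outer_ref, k0, c=1e-3), wave_c1e3)
        db = composite_deviation(compose(outer_ref, kb, c=1e-3), wave_c1e3)
        # both gauges agree with the true wave to leading order
        assert d0["max"] < 0.1 and db["max"] < 0.15

    def test_peak_gauge_meets_peak(self, constants):
        c = 1e-3
        k7 = peak_adapted_k7(c, constants)
        _, U3 = layer3_leading(np.array([0.0]),
                               constants.with_gauges(k7=k7))
        p = constants.params
        assert U3[0] == pytest.approx(constants.k6 - p.nu * c, rel=1e-10)
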