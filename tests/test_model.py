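"""Model definitions: steady states, kernel, dispersion, basins."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from drylandwaves import (DomainError, ParameterError, Params,
                          classify_basin, convolution_residual,
                          kernel_multiplier, laplace_kernel,
                          linear_dispersion, nonspatial_rhs,
                          uniform_steady_states, vegetated_state)
from drylandwaves.model import periodic_convolve


def make_params(a=1.2, b=0.45, nu=18.25, d=0.5625, eta=0.75, c=0.0):
    return Params(a=a, b=b, nu=nu, d=d, eta=eta, c=c)


class TestParams:
    def test_alpha_derived(self):
        p = make_params()
        assert p.alpha == p.b + p.d

    @pytest.mark.parametrize("bad", [
        dict(a=-1.0), dict(b=0.0), dict(d=-0.1), dict(eta=0.0),
        dict(nu=-1.0), dict(c=-1e-3),
    ])
    def test_invalid_rejected(self, bad):
        kw = dict(a=1.2, b=0.45, nu=18.25, d=0.5625, eta=0.75, c=0.0)
        kw.update(bad)
        with pytest.raises(ParameterError):
            Params(**kw)

    @pytest.mark.parametrize("suffix", [".json", ".ini"])
    def test_config_roundtrip(self, tmp_path, suffix):
        p = make_params(a=0.727, c=1e-3)
        path = tmp_path / f"params{suffix}"
        p.to_file(path)
        q = Params.from_file(path)
        assert q == p


class TestSteadyStates:
    def test_low_rainfall_only_bare_state(self):
        # a < 2b: the desert state is the only uniform equilibrium
        states = uniform_steady_states(make_params(a=0.727, b=0.45))
        assert len(states) == 1
        assert states[0].w == 0.727 and states[0].u == 0.0

    def test_threshold_double_root(self):
        states = uniform_steady_states(make_params(a=0.9, b=0.45))
        veg = [s for s in states if s.u > 0]
        assert len(veg) == 1
        assert veg[0].u == pytest.approx(1.0)
        assert veg[0].w == pytest.approx(0.45)

    def test_vegetated_roots_against_polynomial_oracle(self):
        p = make_params(a=1.2, b=0.45)
        states = uniform_steady_states(p)
        veg = sorted(s.u for s in states if s.u > 0)
        # oracle: roots of b u^2 - a u + b
        oracle = sorted(r for r in np.roots([p.b, -p.a, p.b]) if r > 0)
        assert veg == pytest.approx(oracle, rel=1e-12)
        for s in states:
            dw, du = nonspatial_rhs(s.w, s.u, p)
            assert abs(dw) < 1e-12 and abs(du) < 1e-12

    def test_stability_labels(self):
        p = make_params(a=1.2, b=0.45)
        labels = {round(s.u, 6): s.stability_label
                  for s in uniform_steady_states(p)}
        veg = vegetated_state(p)
        assert labels[0.0] == "stable"
        assert labels[round(veg.u, 6)] == "stable"
        other = [s for s in uniform_steady_states(p)
                 if s.u > 0 and s.u != veg.u][0]
        assert other.stability_label in ("unstable", "saddle")


class TestKinetics:
    def test_plant_free_state_is_equilibrium(self):
        p = make_params(a=0.727, b=0.45)
        assert nonspatial_rhs(p.a, 0.0, p) == (0.0, 0.0)

    def test_direct_arithmetic(self):
        p = make_params(a=0.727, b=0.45)
        dw, du = nonspatial_rhs(1.0, 1.0, p)
        assert dw == pytest.approx(0.727 - 1.0 - 1.0)
        assert du == pytest.approx(1.0 - 0.45)


class TestBasins:
    def test_fixed_points_classified_trivially(self):
        p = make_params(a=1.2, b=0.45)
        veg = vegetated_state(p)
        assert classify_basin(veg.w, veg.u, p) == "veg"
        assert classify_basin(p.a, 0.0, p) == "no_veg"

    def test_requires_vegetated_attractor(self):
        with pytest.raises(DomainError):
            classify_basin(0.5, 0.5, make_params(a=0.7, b=0.45))

    def test_grid_against_long_horizon_oracle(self):
        p = make_params(a=1.2, b=0.45)
        veg = vegetated_state(p)

        def oracle(w, u):
            sol = solve_ivp(lambda t, y: nonspatial_rhs(y[0], y[1], p),
                            (0, 4000.0), [w, u], rtol=1e-11, atol=1e-12)
            wf, uf = sol.y[:, -1]
            if math.hypot(wf - veg.w, uf - veg.u) < 1e-4:
                return "veg"
            if math.hypot(wf - p.a, uf) < 1e-4:
                return "no_veg"
            return "boundary"

        rng = np.random.default_rng(7)
        pts = np.column_stack([rng.uniform(0.0, 2.5, 12),
                               rng.uniform(0.0, 2.5, 12)])
        for w, u in pts:
            got = classify_basin(w, u, p)
            if got != "boundary":  # near-separatrix points are ambiguous
                assert got == oracle(w, u)


class TestKernel:
    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_normalization(self, eta):
        val, _ = quad(lambda x: laplace_kernel(x, eta), -50 / eta, 50 / eta)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_value_and_symmetry(self):
        assert laplace_kernel(0.0, 0.75) == pytest.approx(0.375)
        xs = np.linspace(0.1, 20, 17)
        assert laplace_kernel(xs, 0.75) == pytest.approx(
            laplace_kernel(-xs, 0.75))

    def test_eta_must_be_positive(self):
        with pytest.raises(ParameterError):
            laplace_kernel(1.0, 0.0)


class TestKernelMultiplier:
    def test_limits(self):
        assert kernel_multiplier(0.0, 0.75, 0.5625) == 0.0
        assert kernel_multiplier(1e6, 0.75, 0.5625) == pytest.approx(
            -0.5625, rel=1e-9)

    def test_against_quadrature_oracle(self):
        # d * (Fourier transform of the kernel at k minus 1)
        eta, d = 0.75, 0.5625
        for k in (0.3, 1.0, 2.5):
            re, _ = quad(lambda x: laplace_kernel(x, eta) * math.cos(k * x),
                         -60 / eta, 60 / eta, limit=400)
            assert kernel_multiplier(k, eta, d) == pytest.approx(
                d * (re - 1.0), abs=1e-7)


class TestLinearDispersion:
    def test_k_zero_equals_kinetic_jacobian(self):
        p = make_params(a=1.2, b=0.45)
        s = vegetated_state(p)
        eigs = linear_dispersion(p, 0.0)
        J = np.array([[-1 - s.u ** 2, -2 * s.u * s.w],
                      [s.u ** 2, 2 * s.u * s.w - p.b]])
        expected = sorted(np.linalg.eigvals(J), key=lambda z: -z.real)
        assert np.allclose(eigs, expected)

    def test_advection_makes_eigenvalues_complex(self):
        p = make_params(a=1.2, b=0.45, nu=18.25)
        eigs = linear_dispersion(p, 0.8)
        assert np.abs(eigs.imag).max() > 1e-6

    def test_local_and_nonlocal_agree_for_narrow_kernel(self):
        # eta -> infinity: the nonlocal multiplier -> 0 like diffusion at
        # small k; compare both against a direct eigen-decomposition
        p = make_params(a=1.2, b=0.45, eta=500.0)
        k = 0.05
        nl = linear_dispersion(p, k)
        loc = linear_dispersion(p, k, local=True)
        # the multipliers differ by d k^2 eta^2/(eta^2+k^2) - ... ~ k^2
        assert np.allclose(nl, loc, atol=5e-3)


class TestConvolutionResidual:
    def test_constant_field(self):
        u = np.full(128, 1.7)
        j = periodic_convolve(u, 0.75, 0.1)
        assert convolution_residual(u, j, 0.75, 0.1) < 1e-12

    def test_second_order_refinement(self):
        eta = 0.75
        errs = []
        for n in (256, 512, 1024):
            L = 2 * math.pi * 8
            dx = L / n
            x = np.arange(n) * dx
            u = 1.5 + np.sin(2 * math.pi * x / L)
            j = periodic_convolve(u, eta, dx)
            errs.append(convolution_residual(u, j, eta, dx))
        order = np.log2(errs[0] / errs[2]) / 2
        assert order > 1.5  # O(dx^2)

    def test_identity_violated_for_j_equal_u(self):
        n = 256
        dx = 2 * math.pi * 8 / n
        x = np.arange(n) * dx
        u = 1.5 + np.sin(x / 8)
        res = convolution_residual(u, u, 0.75, dx)
        # residual equals ||u''|| = 1/64 when j = u (control case)
        assert res == pytest.approx(1.0 / 64.0, rel=0.05)
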