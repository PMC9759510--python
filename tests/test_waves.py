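"""Travelling-wave BVP: entry, solving, continuation, diagnostics."""

import math

import numpy as np
import pytest

from drylandwaves import DomainError
from drylandwaves.waves import (Branch, WaveProfile, continue_branch,
                                hopf_guess, hopf_locus, scaling_exponents,
                                solve_periodic_wave, tw_jacobian, tw_rhs,
                                wave_properties, _critical_pair)


class TestTwRhs:
    def test_steady_state_is_fixed_point(self, fig2_params):
        p = fig2_params.replace(a=1.2, c=0.1)
        from drylandwaves.model import vegetated_state
        s = vegetated_state(p)
        derivs = tw_rhs((s.w, s.u, s.u, 0.0), p)
        assert np.allclose(derivs, 0.0, atol=1e-14)

    def test_bare_state_water_component(self, fig2_params):
        p = fig2_params.replace(c=0.1)
        dW, _, _, _ = tw_rhs((p.a, 0.0, 0.0, 0.0), p)
        assert dW == 0.0

    def test_zero_speed_redirected_to_outer(self, fig2_params):
        with pytest.raises(DomainError):
            tw_rhs((1.0, 1.0, 1.0, 0.0), fig2_params.replace(c=0.0))

    def test_jacobian_matches_finite_differences(self, fig2_params):
        p = fig2_params.replace(c=0.05)
        y0 = np.array([0.3, 1.4, 1.2, -0.2])
        jac = tw_jacobian(y0, p)
        eps = 1e-7
        for j in range(4):
            dy = np.zeros(4)
            dy[j] = eps
            fd = (np.array(tw_rhs(y0 + dy, p))
                  - np.array(tw_rhs(y0 - dy, p))) / (2 * eps)
            assert np.allclose(jac[:, j], fd, rtol=1e-5, atol=1e-5)


class TestHopf:
    def test_eigenvalues_cross_at_locus(self, fig2_params):
        a_h = hopf_locus(fig2_params, c=0.1)
        re, im, _ = _critical_pair(fig2_params.replace(a=a_h, c=0.1))
        assert abs(re) < 1e-8
        assert im > 0

    def test_guess_construction(self, fig2_params):
        g = hopf_guess(fig2_params, c=0.1, rel_amplitude=0.01)
        from drylandwaves.model import vegetated_state
        s = vegetated_state(g.params)
        amp = (g.U.max() - g.U.min()) / 2
        assert amp == pytest.approx(0.01 * s.u, rel=1e-6)
        _, im, _ = _critical_pair(g.params)
        assert g.L == pytest.approx(2 * math.pi / im)


class TestSolvePeriodicWave:
    def test_resolving_own_output_is_fixed_point(self, wave_c01):
        again = solve_periodic_wave(wave_c01.params, wave_c01)
        assert again.L == pytest.approx(wave_c01.L, rel=1e-8)
        assert np.interp(0.37, again.s_mesh, again.U) == pytest.approx(
            np.interp(0.37, wave_c01.s_mesh, wave_c01.U), rel=1e-5)

    def test_translation_gauge_unique_modulo_shift(self, wave_c01):
        # shift the guess by a third of a period; the converged profile
        # must agree with the original after re-alignment at the spike
        g = wave_c01
        shift = 0.37
        s = np.mod(g.s_mesh + shift, 1.0)
        order = np.argsort(s)
        shifted = WaveProfile(s[order], g.W[order], g.U[order], g.J[order],
                              g.M[order], L=g.L, c=g.c, params=g.params)
        sol = solve_periodic_wave(g.params, shifted)
        assert sol.L == pytest.approx(g.L, rel=1e-6)
        for s_probe in (0.2, 0.5, 0.8):
            assert np.interp(s_probe, sol.s_mesh, sol.U) == pytest.approx(
                np.interp(s_probe, g.s_mesh, g.U), rel=1e-4)

    def test_fields_positive(self, branch):
        for prof in branch.profiles:
            assert prof.U.min() > 0
            assert prof.W.min() > 0


class TestContinuation:
    def test_wavelength_monotone_in_rainfall(self, wave_c1e3):
        # pattern wavelength shrinks as rainfall increases
        br = continue_branch(wave_c1e3, "a", [0.76, 0.80])
        assert br.complete
        Ls = [wave_c1e3.L] + list(br.wavelengths)
        assert Ls[0] > Ls[1] > Ls[2]

    def test_two_step_equals_one_step(self, wave_c01):
        one = continue_branch(wave_c01, "c", [0.05])
        two = continue_branch(wave_c01, "c", [0.075, 0.05])
        assert one.profiles[-1].L == pytest.approx(
            two.profiles[-1].L, rel=1e-6)

    def test_targets_must_be_monotone(self, wave_c01):
        with pytest.raises(DomainError):
            continue_branch(wave_c01, "c", [0.05, 0.2, 0.01])


class TestWaveProperties:
    def test_translation_equivariance(self, wave_c01):
        g = wave_c01
        props = wave_properties(g)
        shift = 0.25
        s = np.mod(g.s_mesh + shift, 1.0)
        order = np.argsort(s)
        rolled = WaveProfile(s[order], g.W[order], g.U[order], g.J[order],
                             g.M[order], L=g.L, c=g.c, params=g.params)
        props2 = wave_properties(rolled)
        assert props2["L"] == props["L"]
        assert props2["maxU"] == pytest.approx(props["maxU"], rel=1e-6)
        dz = (props2["z_s"] - props["z_s"]) % g.L
        assert dz == pytest.approx(shift * g.L, abs=1e-3 * g.L)

    def test_max_refinement_against_dense_resampling(self, wave_c01):
        props = wave_properties(wave_c01)
        dense = wave_c01.resample(np.linspace(0, 1, 200_001))
        assert props["maxU"] == pytest.approx(dense.U.max(), rel=1e-3)


class TestScalingExponents:
    def test_recovers_exact_power_laws(self, fig2_params):
        # synthetic branch with U ~ 2/c and W-floor ~ 0.1 c^2
        profiles = []
        s = np.linspace(0, 1, 101)
        for c in np.geomspace(1e-4, 1e-2, 7):
            shape = 1 + np.cos(2 * math.pi * s) ** 2
            U = (2.0 / c) * shape
            W = 0.1 * c * c * (2.0 - shape / shape.max())
            profiles.append(WaveProfile(
                s, W, U, np.ones_like(s), np.zeros_like(s), L=7.0, c=c,
                params=fig2_params.replace(c=c)))
        out = scaling_exponents(Branch("c", profiles))
        assert out["slope_maxU"] == pytest.approx(-1.0, abs=1e-9)
        assert out["slope_Wspike"] == pytest.approx(2.0, abs=1e-9)

    def test_requires_sufficient_span(self, fig2_params):
        s = np.linspace(0, 1, 11)
        mk = lambda c: WaveProfile(s, s + 1, s + 1, s, s, L=7.0, c=c,
                                   params=fig2_params.replace(c=c))
        with pytest.raises(DomainError):
            scaling_exponents(Branch("c", [mk(0.01), mk(0.009)]))

    def test_spike_amplitudes_stabilize_along_branch(self, branch):
        # maxU*c and minW/c^2 settle to constants in the asymptotic decade
        sel = [p for p in branch.profiles if p.c <= 1e-3]
        vals_u = [wave_properties(p)["maxU"] * p.c for p in sel]
        vals_w = [wave_properties(p)["minW"] / p.c ** 2 for p in sel]
        assert max(vals_u) / min(vals_u) < 1.1
        assert max(vals_w) / min(vals_w) < 1.1
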