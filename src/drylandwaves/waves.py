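"""Periodic travelling-wave solutions of the reduced dispersal model.

A pattern moving uphill at speed ``c`` is a periodic orbit of the ODE
system in the comoving coordinate ``z = x - c t``::

    (c + nu) W' = U**2 W + W - a
    c U'        = alpha U - d J - U**2 W,   alpha = b + d
    J'          = M
    M'          = eta**2 (J - U)

with ``J`` the dispersal convolution of ``U`` and ``M = J'``.  The spatial
period ``L`` (the pattern wavelength) is an unknown: the orbit is computed
on the fixed domain ``s = z / L in [0, 1]`` as a boundary-value problem
``dY/ds = L F(Y)`` with periodic boundary conditions, ``L`` appended as a
free parameter, and one phase condition (``dU/ds = 0`` at ``s = 0``, the
spike maximum) to remove translation invariance.

As ``c`` decreases, the plant field develops a spike of height ``O(1/c)``
with interior layers of width ``O(c)`` and ``O(c**2)``; ``W`` and ``U``
then span many orders of magnitude across the period.  The collocation
problem is therefore posed in logarithmic variables ``(ln W, ln U, J, M)``,
which turns the exponential layer profiles into nearly linear functions,
enforces positivity, and keeps the Newton system well conditioned down to
``c = 1e-4``.  Solutions enter the family through a small-amplitude guess
at the Hopf bifurcation of the comoving flow, ramped up by amplitude
continuation (spike peak pinned, rainfall free), and are then continued in
``a`` or ``c`` with adaptive geometric steps and monitor-based remeshing.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_bvp

from ._errors import ConvergenceError, DomainError, NotFoundError
from .model import Params, vegetated_state

__all__ = [
    "WaveProfile",
    "Branch",
    "tw_rhs",
    "tw_jacobian",
    "hopf_guess",
    "hopf_locus",
    "enter_branch",
    "solve_periodic_wave",
    "continue_branch",
    "wave_properties",
    "scaling_exponents",
]

logger = logging.getLogger(__name__)

#: below this migration speed the collocation residual estimate at the
#: spike cliff is dominated by floating-point noise; the acceptance
#: tolerance is relaxed accordingly (with a logged warning).
_C_TOL_RELAX = 5e-4
_TOL_FLOOR = 3e-5


@dataclass
class WaveProfile:
    """One period of a travelling wave on the normalized mesh ``s = z/L``."""

    s_mesh: np.ndarray
    W: np.ndarray
    U: np.ndarray
    J: np.ndarray
    M: np.ndarray
    L: float
    c: float
    params: Params
    residual: float = math.nan

    @property
    def z_mesh(self) -> np.ndarray:
        return self.s_mesh * self.L

    @property
    def fields(self) -> np.ndarray:
        """Stacked (4, m) array in the order W, U, J, M."""
        return np.vstack([self.W, self.U, self.J, self.M])

    def resample(self, s_new: np.ndarray) -> "WaveProfile":
        """Resample onto a new normalized mesh.

        ``W`` and ``U`` are interpolated in log space (they are positive
        and vary exponentially through the layers); ``J`` and ``M``
        linearly.
        """
        s_new = np.asarray(s_new, float)
        W = np.exp(np.interp(s_new, self.s_mesh, np.log(self.W)))
        U = np.exp(np.interp(s_new, self.s_mesh, np.log(self.U)))
        J = np.interp(s_new, self.s_mesh, self.J)
        M = np.interp(s_new, self.s_mesh, self.M)
        return WaveProfile(s_new, W, U, J, M, L=self.L, c=self.c,
                           params=self.params, residual=self.residual)

    def remesh(self, n_nodes: int) -> "WaveProfile":
        """Redistribute ``n_nodes`` mesh points by arclength equidistribution.

        The monitor is the total variation of the range-normalized fields
        (``W`` and ``U`` in log space) plus a uniform floor, so that nodes
        concentrate in the spike layers without starving the outer region.
        """
        span = lambda f: (f - f.min()) / max(np.ptp(f), 1e-300)
        mon = np.diff(self.s_mesh).astype(float)
        for f in (np.log(self.W), np.log(self.U), self.J, self.M):
            mon = mon + np.abs(np.diff(span(f)))
        cum = np.concatenate([[0.0], np.cumsum(mon)])
        cum /= cum[-1]
        s_new = np.interp(np.linspace(0.0, 1.0, n_nodes), cum, self.s_mesh)
        s_new[0], s_new[-1] = 0.0, 1.0
        return self.resample(np.unique(s_new))


@dataclass
class Branch:
    """Profiles recorded along a one-parameter continuation."""

    param_name: str
    profiles: list[WaveProfile] = field(default_factory=list)
    complete: bool = True

    @property
    def param_values(self) -> np.ndarray:
        return np.array([getattr(p.params, self.param_name)
                         for p in self.profiles])

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([p.L for p in self.profiles])


def tw_rhs(state, p: Params):
    """Right-hand side of the travelling-wave system (per unit ``z``).

    ``state`` is ``(W, U, J, M)``, scalars or arrays.  Requires ``c > 0``;
    the ``c = 0`` limit replaces the ``U`` equation by an algebraic
    constraint and is handled by the outer boundary-value problem module.
    """
    if p.c <= 0.0:
        raise DomainError("tw_rhs requires c > 0; for c = 0 use the outer "
                          "boundary-value problem (drylandwaves.outer)")
    W, U, J, M = state
    dW = (U * U * W + W - p.a) / (p.c + p.nu)
    dU = (p.alpha * U - p.d * J - U * U * W) / p.c
    dJ = M
    dM = p.eta * p.eta * (J - U)
    return dW, dU, dJ, dM


def tw_jacobian(state, p: Params):
    """Jacobian of :func:`tw_rhs` with respect to ``(W, U, J, M)``.

    Returns an array of shape ``(4, 4) + shape_of_fields``.
    """
    W, U, J, M = [np.asarray(v, float) for v in state]
    zero = np.zeros(np.broadcast(W, U).shape)
    one = zero + 1.0
    cn = p.c + p.nu
    row1 = [(U * U + 1.0) / cn, 2.0 * U * W / cn, zero, zero]
    row2 = [-U * U / p.c, (p.alpha - 2.0 * U * W) / p.c,
            zero - p.d / p.c, zero]
    row3 = [zero, zero, zero, one]
    row4 = [zero, zero - p.eta ** 2, zero + p.eta ** 2, zero]
    return np.array([row1, row2, row3, row4])


def _tw_linearization_matrix(p: Params):
    """4x4 Jacobian of the comoving flow at the vegetated steady state."""
    s = vegetated_state(p)
    W, U = s.w, s.u
    J = np.zeros((4, 4))
    cn = p.c + p.nu
    J[0] = [(U * U + 1.0) / cn, 2.0 * U * W / cn, 0.0, 0.0]
    J[1] = [-U * U / p.c, (p.alpha - 2.0 * U * W) / p.c, -p.d / p.c, 0.0]
    J[2] = [0.0, 0.0, 0.0, 1.0]
    J[3] = [0.0, -p.eta ** 2, p.eta ** 2, 0.0]
    return J


def _critical_pair(p: Params):
    """The complex-conjugate eigenpair closest to the imaginary axis.

    Returns ``(re, im, eigvec)`` for the member with positive imaginary
    part, or ``None`` if the spectrum is entirely real.
    """
    vals, vecs = np.linalg.eig(_tw_linearization_matrix(p))
    idx = [i for i, v in enumerate(vals) if v.imag > 1e-12]
    if not idx:
        return None
    i = min(idx, key=lambda i: abs(vals[i].real))
    return vals[i].real, vals[i].imag, vecs[:, i]


def hopf_locus(p: Params, c: float, a_range=(None, None), *, n_scan=200,
               tol=1e-10) -> float:
    """Rainfall value where the comoving flow undergoes a Hopf bifurcation.

    Scans ``a`` over ``a_range`` (default ``(2b + eps, 4)``) at fixed ``c``
    for a sign change in the real part of the complex eigenpair of the
    travelling-wave linearization, then bisects to ``|Re lambda| < tol``.
    """
    a_lo = a_range[0] if a_range[0] is not None else 2.0 * p.b * (1 + 1e-6)
    a_hi = a_range[1] if a_range[1] is not None else 4.0

    def re_part(a):
        pair = _critical_pair(p.replace(a=a, c=c))
        return None if pair is None else pair[0]

    grid = np.linspace(a_lo, a_hi, n_scan)
    vals = [re_part(a) for a in grid]
    bracket = None
    for (a0, r0), (a1, r1) in zip(zip(grid, vals), zip(grid[1:], vals[1:])):
        if r0 is None or r1 is None:
            continue
        if r0 == 0.0:
            return a0
        if r0 * r1 < 0:
            bracket = (a0, a1, r0)
            break
    if bracket is None:
        raise NotFoundError(
            f"no Hopf crossing of the comoving linearization found for "
            f"a in [{a_lo}, {a_hi}] at c={c}")
    a0, a1, r0 = bracket
    while a1 - a0 > 1e-14:
        am = 0.5 * (a0 + a1)
        rm = re_part(am)
        if rm is None:
            break
        if abs(rm) < tol:
            return am
        if rm * r0 > 0:
            a0, r0 = am, rm
        else:
            a1 = am
    return 0.5 * (a0 + a1)


def hopf_guess(p: Params, c: float, *, rel_amplitude=1e-2, n_mesh=201,
               a_range=(None, None)) -> WaveProfile:
    """Small-amplitude initial guess for the periodic-wave BVP.

    Locates the Hopf bifurcation in ``a`` at fixed ``c``, then returns a
    sinusoidal perturbation of the vegetated steady state along the
    critical eigenvector, with period ``2 pi / Im(lambda)``.  The returned
    profile carries the Hopf-point parameters; it is meant as a BVP guess,
    not a converged solution.
    """
    a_h = hopf_locus(p, c, a_range)
    ph = p.replace(a=a_h, c=c)
    re, om, vec = _critical_pair(ph)
    s = vegetated_state(ph)
    base = np.array([s.w, s.u, s.u, 0.0])
    # scale the eigenvector so the U-component perturbation is relative
    vec = vec / abs(vec[1]) * (rel_amplitude * s.u)
    sm = np.linspace(0.0, 1.0, n_mesh)
    # cosine phase in U at s=0 => dU/ds(0) = 0, matching the phase condition
    phase = np.exp(2j * math.pi * sm - 1j * np.angle(vec[1]))
    Y = base[:, None] + np.real(vec[:, None] * phase)
    L = 2.0 * math.pi / abs(om)
    return WaveProfile(sm, Y[0], Y[1], Y[2], Y[3], L=L, c=c, params=ph)


def _roll_peak_to_seam(profile: WaveProfile) -> WaveProfile:
    """Cyclically shift a profile so that max(U) sits at s = 0 (and 1)."""
    g = profile
    i0 = int(np.argmax(g.U))
    m = g.U.size
    if i0 in (0, m - 1):
        return g
    sm = g.s_mesh
    Y = g.fields
    # drop the duplicated endpoint, roll, re-close the period
    s_open = sm[:-1]
    Y_open = Y[:, :-1]
    s_new = np.mod(s_open - s_open[i0], 1.0)
    order = np.argsort(s_new)
    s_new = s_new[order]
    Y_new = Y_open[:, order]
    s_new = np.concatenate([s_new, [1.0]])
    Y_new = np.column_stack([Y_new, Y_new[:, 0]])
    keep = np.concatenate([[True], np.diff(s_new) > 1e-13])
    return WaveProfile(s_new[keep], *Y_new[:, keep], L=g.L, c=g.c,
                       params=g.params, residual=g.residual)


def _effective_tol(c: float, tol: float) -> float:
    if c < _C_TOL_RELAX and tol < _TOL_FLOOR:
        logger.warning("relaxing BVP tolerance to %g for c=%g",
                       _TOL_FLOOR, c)
        return _TOL_FLOOR
    return tol


def solve_periodic_wave(p: Params, guess: WaveProfile, *, tol=1e-6,
                        max_nodes=60_000) -> WaveProfile:
    """Solve the free-period periodic BVP from an initial guess.

    The system ``dY/ds = L F(Y)`` is solved on ``s in [0, 1]`` in the
    variables ``(ln W, ln U, J, M)`` by adaptive collocation, with the
    wavelength ``L`` as a free parameter, periodic boundary conditions on
    all four fields and the phase condition ``dU/ds(0) = 0`` (the guess is
    rolled so its ``U``-maximum sits at the periodic seam, which the
    condition then pins).
    """
    if p.c <= 0:
        raise DomainError("solve_periodic_wave requires c > 0")
    a, al, d, eta, nu, c = p.a, p.alpha, p.d, p.eta, p.nu, p.c

    def fun(x, y, pars):
        L = pars[0]
        P, V, J, M = y
        eV = np.exp(V)
        eP = np.exp(P)
        return L * np.vstack([(eV * eV + 1.0 - a / eP) / (c + nu),
                              (al - d * J / eV - eV * eP) / c,
                              M, eta * eta * (J - eV)])

    def fun_jac(x, y, pars):
        L = pars[0]
        P, V, J, M = y
        eV = np.exp(V)
        eP = np.exp(P)
        z = np.zeros_like(P)
        o = np.ones_like(P)
        jac = np.array([
            [a / eP / (c + nu), 2.0 * eV * eV / (c + nu), z, z],
            [-eV * eP / c, (d * J / eV - eV * eP) / c, -d / eV / c, z],
            [z, z, z, o],
            [z, -eta * eta * eV, eta * eta * o, z]])
        dfdp = (fun(x, y, pars) / L)[:, None, :]
        return L * jac, dfdp

    def bc(ya, yb, pars):
        phase = al - d * ya[2] / np.exp(ya[1]) - np.exp(ya[1] + ya[0])
        return np.array([*(ya - yb), phase])

    def bc_jac(ya, yb, pars):
        dya = np.zeros((5, 4))
        dyb = np.zeros((5, 4))
        dya[:4, :4] = np.eye(4)
        dyb[:4, :4] = -np.eye(4)
        eV = np.exp(ya[1])
        eP = np.exp(ya[0])
        dya[4] = [-eV * eP, d * ya[2] / eV - eV * eP, -d / eV, 0.0]
        return dya, dyb, np.zeros((5, 1))

    g = _roll_peak_to_seam(guess)
    if g.W.min() <= 0 or g.U.min() <= 0:
        raise DomainError("guess must have strictly positive W and U")
    Y = np.vstack([np.log(g.W), np.log(g.U), g.J, g.M])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sol = solve_bvp(fun, bc, g.s_mesh, Y, p=[g.L], fun_jac=fun_jac,
                        bc_jac=bc_jac, tol=_effective_tol(c, tol),
                        max_nodes=max_nodes)
    if sol.status != 0:
        raise ConvergenceError(
            f"periodic-wave BVP failed at c={p.c}: {sol.message}",
            residual=float(np.max(sol.rms_residuals))
            if sol.rms_residuals is not None else None)
    L = float(sol.p[0])
    if L <= 0:
        raise ConvergenceError(f"non-positive period L={L} rejected")
    P, V, J, M = sol.y
    return WaveProfile(sol.x, np.exp(P), np.exp(V), J, M, L=L, c=p.c,
                       params=p, residual=float(np.max(sol.rms_residuals)))


def _solve_fixed_peak(p: Params, guess: WaveProfile, peak: float, *,
                      tol=1e-6, max_nodes=60_000) -> WaveProfile:
    """Solve the periodic BVP with the spike peak pinned and ``a`` free.

    Used to enter the wave branch near the Hopf bifurcation, where the
    ordinary formulation (fixed ``a``, free ``L``) collapses onto the
    spatially uniform solution: pinning ``U(0) = peak`` excludes the
    uniform state, and the rainfall ``a`` joins ``L`` as a free parameter.
    """
    al, d, eta, nu, c = p.alpha, p.d, p.eta, p.nu, p.c
    log_peak = math.log(peak)

    def fun(x, y, pars):
        L, a = pars
        P, V, J, M = y
        eV = np.exp(V)
        eP = np.exp(P)
        return L * np.vstack([(eV * eV + 1.0 - a / eP) / (c + nu),
                              (al - d * J / eV - eV * eP) / c,
                              M, eta * eta * (J - eV)])

    def fun_jac(x, y, pars):
        L, a = pars
        P, V, J, M = y
        eV = np.exp(V)
        eP = np.exp(P)
        z = np.zeros_like(P)
        o = np.ones_like(P)
        jac = np.array([
            [a / eP / (c + nu), 2.0 * eV * eV / (c + nu), z, z],
            [-eV * eP / c, (d * J / eV - eV * eP) / c, -d / eV / c, z],
            [z, z, z, o],
            [z, -eta * eta * eV, eta * eta * o, z]])
        dfdp = np.zeros((4, 2) + x.shape)
        dfdp[:, 0] = fun(x, y, pars) / L
        dfdp[0, 1] = -L / eP / (c + nu)
        return L * jac, dfdp

    def bc(ya, yb, pars):
        phase = al - d * ya[2] / np.exp(ya[1]) - np.exp(ya[1] + ya[0])
        return np.array([*(ya - yb), phase, ya[1] - log_peak])

    def bc_jac(ya, yb, pars):
        dya = np.zeros((6, 4))
        dyb = np.zeros((6, 4))
        dya[:4, :4] = np.eye(4)
        dyb[:4, :4] = -np.eye(4)
        eV = np.exp(ya[1])
        eP = np.exp(ya[0])
        dya[4] = [-eV * eP, d * ya[2] / eV - eV * eP, -d / eV, 0.0]
        dya[5, 1] = 1.0
        return dya, dyb, np.zeros((6, 2))

    g = _roll_peak_to_seam(guess)
    Y = np.vstack([np.log(g.W), np.log(g.U), g.J, g.M])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sol = solve_bvp(fun, bc, g.s_mesh, Y, p=[g.L, g.params.a],
                        fun_jac=fun_jac, bc_jac=bc_jac, tol=tol,
                        max_nodes=max_nodes)
    if sol.status != 0:
        raise ConvergenceError(f"fixed-peak BVP failed: {sol.message}")
    L, a = float(sol.p[0]), float(sol.p[1])
    if not (0.0 < a < 10.0 and 0.0 < L < 1e3):
        raise ConvergenceError(f"fixed-peak solve wandered off-branch "
                               f"(a={a:.3g}, L={L:.3g})")
    P, V, J, M = sol.y
    return WaveProfile(sol.x, np.exp(P), np.exp(V), J, M, L=L, c=p.c,
                       params=p.replace(a=a),
                       residual=float(np.max(sol.rms_residuals)))


def enter_branch(p: Params, c: float, *, tol=1e-6, max_nodes=60_000,
                 a_tol=1e-8) -> WaveProfile:
    """Obtain a converged wave at ``(p.a, c)`` starting from the Hopf point.

    The only analytically available entry to the wave family is the
    small-amplitude onset at the Hopf bifurcation of the comoving flow.
    From there the spike peak ``U(0)`` is ramped up with the rainfall free
    (secant prediction of the peak that lands on the requested ``a``,
    capped at 50% growth per step, halved on failure), and a final solve at
    fixed ``a`` polishes the profile.
    """
    a_target = p.a
    guess = hopf_guess(p, c, rel_amplitude=0.05)
    peak = float(guess.U.max())
    prof = _solve_fixed_peak(p.replace(c=c), guess, peak, tol=tol,
                             max_nodes=max_nodes)
    history = [(peak, prof.params.a)]
    for _ in range(60):
        a_now = prof.params.a
        if abs(a_now - a_target) < a_tol:
            break
        if len(history) >= 2:
            (A0, a0), (A1, a1) = history[-2], history[-1]
            slope = (a1 - a0) / (A1 - A0) if A1 != A0 else 0.0
        else:
            slope = 0.0
        if slope < 0:
            proposal = peak + (a_target - a_now) / slope
            proposal = min(proposal, 1.5 * peak)
            proposal = max(proposal, peak / 1.5)
        else:
            proposal = 1.5 * peak  # pre-fold: grow the amplitude
        step = proposal / peak
        while True:
            try:
                cand = _solve_fixed_peak(p.replace(c=c), prof, peak * step,
                                         tol=tol, max_nodes=max_nodes)
                break
            except ConvergenceError:
                step = 1.0 + (step - 1.0) / 2.0
                if abs(step - 1.0) < 1e-4:
                    raise
        peak *= step
        prof = cand
        history.append((peak, prof.params.a))
        logger.info("branch entry: peak=%.4f a=%.6f L=%.4f", peak,
                    prof.params.a, prof.L)
    else:
        raise ConvergenceError(
            f"branch entry failed to reach a={a_target} within 60 steps")
    return solve_periodic_wave(p.replace(c=c), prof, tol=tol,
                               max_nodes=max_nodes)


def continue_branch(start: WaveProfile, param_name: str, targets,
                    *, tol=1e-6, max_nodes=60_000, n_remesh=4000,
                    max_halvings=10, keep_intermediate=False) -> Branch:
    """Continue a converged wave in one parameter through a list of targets.

    Steps geometrically for ``c`` (the spike width scales with ``c`` and
    ``c**2``, so uniform steps fail) and linearly for other parameters,
    halving the step on solver failure.  Before each solve the previous
    profile is remeshed by monitor equidistribution onto ``n_remesh``
    nodes, so the node count stays bounded along the branch.  Returns a
    :class:`Branch` whose profiles are the converged solutions at each
    requested target (plus intermediate accepted steps if
    ``keep_intermediate``).
    """
    targets = list(targets)
    value = getattr(start.params, param_name)
    if len(targets) > 1:
        diffs = np.sign(np.diff(targets))
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise DomainError("targets must be strictly monotone")
    geometric = param_name == "c"
    branch = Branch(param_name=param_name, profiles=[])
    if math.isclose(value, targets[0], rel_tol=1e-12):
        branch.profiles.append(start)
        targets = targets[1:]
    current = start
    for target in targets:
        while not math.isclose(value, target, rel_tol=1e-12, abs_tol=0.0):
            if geometric:
                full = math.log(target / value)
                step = max(min(full, math.log(2.0)), -math.log(2.0))
            else:
                step = target - value
            halvings = 0
            while True:
                trial = value * math.exp(step) if geometric else value + step
                if geometric and abs(math.log(target / trial)) < 1e-12:
                    trial = target
                p_trial = current.params.replace(**{param_name: trial})
                try:
                    guess = current.remesh(n_remesh)
                    prof = solve_periodic_wave(p_trial, guess, tol=tol,
                                               max_nodes=max_nodes)
                    break
                except ConvergenceError as err:
                    halvings += 1
                    if halvings > max_halvings:
                        logger.error("continuation stalled at %s=%g: %s",
                                     param_name, value, err)
                        branch.complete = False
                        return branch
                    step *= 0.5
            value = trial
            current = prof
            logger.info("continuation %s=%-12g L=%.6f nodes=%d residual=%.2e",
                        param_name, value, prof.L, prof.s_mesh.size,
                        prof.residual)
            at_target = math.isclose(value, target, rel_tol=1e-12)
            if keep_intermediate and not at_target:
                branch.profiles.append(prof)
        branch.profiles.append(current)
    return branch


def wave_properties(profile: WaveProfile) -> dict:
    """Wavelength, extrema and spike location of a converged profile.

    Extrema are refined by a local quadratic fit through the mesh maximum
    and its neighbours; ``z_s`` is the refined location (in ``z`` units) of
    the ``U`` maximum.  ``W_at_spike`` is the water density at ``z_s``.
    """

    def refine_max(s, f):
        i = int(np.argmax(f))
        if i == 0 or i == f.size - 1:
            # spike pinned at the periodic seam: wrap neighbours
            sm = np.array([s[-2] - 1.0, s[0], s[1]]) if i == 0 else \
                 np.array([s[-2], s[-1], s[1] + 1.0])
            fm = np.array([f[-2], f[0], f[1]]) if i == 0 else \
                 np.array([f[-2], f[-1], f[1]])
        else:
            sm, fm = s[i - 1:i + 2], f[i - 1:i + 2]
        coef = np.polyfit(sm - sm[1], fm, 2)
        if coef[0] >= 0:  # degenerate; fall back to mesh value
            return s[i] % 1.0, f[i]
        ds = -coef[1] / (2.0 * coef[0])
        ds = float(np.clip(ds, sm[0] - sm[1], sm[2] - sm[1]))
        return (sm[1] + ds) % 1.0, float(np.polyval(coef, ds))

    s_max, u_max = refine_max(profile.s_mesh, profile.U)
    _, w_max = refine_max(profile.s_mesh, profile.W)
    w_at_spike = float(np.exp(np.interp(s_max, profile.s_mesh,
                                        np.log(profile.W))))
    return {
        "L": profile.L,
        "maxU": u_max,
        "minU": float(profile.U.min()),
        "maxW": w_max,
        "minW": float(profile.W.min()),
        "z_s": s_max * profile.L,
        "W_at_spike": w_at_spike,
    }


def scaling_exponents(branch: Branch) -> dict:
    """Log-log slopes of spike height and spike water level against ``c``.

    The spike height grows like ``1/c`` and the water density at the spike
    base shrinks like ``c**2`` as the migration speed tends to zero.  The
    latter is measured as the period minimum of ``W``: the minimum sits at
    the downhill foot of the spike where water uptake balances rainfall
    (``U**2 W = a``), which is the regime with the ``c**2`` scaling; at the
    exact ``U``-maximum the stationarity of ``U`` instead forces
    ``W = alpha/U = O(c)``.  Fits least-squares slopes of ``log(maxU)``
    and ``log(min W)`` against ``log c`` along a branch spanning at least
    1.5 decades.
    """
    if branch.param_name != "c":
        raise DomainError("scaling exponents require a branch in c")
    cs = branch.param_values
    if cs.size < 3 or (np.log10(cs.max()) - np.log10(cs.min())) < 1.5:
        raise DomainError("branch must span at least 1.5 decades in c")
    props = [wave_properties(p) for p in branch.profiles]
    logc = np.log(cs)
    slope_maxU = np.polyfit(logc, np.log([pr["maxU"] for pr in props]), 1)[0]
    slope_W = np.polyfit(logc, np.log([pr["minW"] for pr in props]), 1)[0]
    return {"slope_maxU": float(slope_maxU), "slope_Wspike": float(slope_W)}
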