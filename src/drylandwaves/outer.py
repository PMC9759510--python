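"""The zero-speed ("outer") boundary-value problem and the critical d*.

Setting the migration speed ``c = 0`` in the travelling-wave equations
reduces them to a third-order system for water ``W_out``, dispersal flux
``J_out`` and its derivative ``M_out`` on one period ``z in [0, L]``::

    nu W_out' = U_out**2 W_out + W_out - a
    J_out'    = M_out
    M_out'    = eta**2 (J_out - U_out)

closed by the algebraic relation ``alpha U = d J + U**2 W``, a quadratic in
``U_out`` whose minus root is the physical branch throughout the outer
region.  The spike of the full travelling wave collapses onto the domain
boundary: matching to the interior layers supplies the four boundary
conditions

    W(L) = 0,  W(0) J(0) = alpha**2 / (4 d),  J(L) = J(0),
    M(L) = M(0) + eta**2 nu W(0) / alpha,

and the wavelength ``L`` is the free unknown.  Real solutions require the
discriminant ``alpha**2 - 4 d J W >= 0`` everywhere, which fails for
dispersal rates above a finite critical value ``d*``; d* is located as the
zero of the (analytic) derivative of the discriminant at ``z = 0``.

The ``M`` condition encodes the jump of the dispersal-flux derivative
across the spike: crossing the spike, ``M' = eta**2 (J - U)`` integrates
the ``O(1)`` plant mass ``k1/alpha`` concentrated in the layers
(``k1 = nu W(0)``), so ``M(L) = M(0) + eta**2 nu W(0) / alpha``.  This is
the form implied by the layer-2 solution itself and verified against
small-c continuation profiles (the jump matches to 0.05% at ``c = 1e-4``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_bvp

from ._errors import (ComplexRootError, ConvergenceError, DomainError,
                      NotFoundError)
from .model import Params

__all__ = [
    "OuterGuess",
    "OuterSolution",
    "u_out_roots",
    "outer_rhs",
    "solve_outer",
    "discriminant_slope_at_origin",
    "find_dstar",
]

logger = logging.getLogger(__name__)

#: numerical floor standing in for the exact boundary value W(L) = 0
#: (removable singularity of the quadratic at W = 0)
W_FLOOR = 1e-12


@dataclass
class OuterGuess:
    """A 3-field initial guess for :func:`solve_outer`."""

    z: np.ndarray
    W: np.ndarray
    J: np.ndarray
    M: np.ndarray
    L: float


@dataclass
class OuterSolution:
    """Converged solution of the c = 0 outer problem on ``[0, L]``."""

    z_mesh: np.ndarray
    W_out: np.ndarray
    J_out: np.ndarray
    M_out: np.ndarray
    L: float
    params: Params
    residual: float = math.nan

    @property
    def U_out(self) -> np.ndarray:
        """Plant density from the minus root of the quadratic closure."""
        return u_out_roots(self.W_out, self.J_out, self.params)[1]

    @property
    def s_mesh(self) -> np.ndarray:
        return self.z_mesh / self.L

    # boundary values (z -> 0+ and z -> L-)
    @property
    def W0(self) -> float: return float(self.W_out[0])

    @property
    def J0(self) -> float: return float(self.J_out[0])

    @property
    def M0(self) -> float: return float(self.M_out[0])

    @property
    def U0(self) -> float:
        # the boundary condition W0 J0 = alpha^2/(4d) makes the
        # discriminant vanish at z = 0: U0 is the double root
        return float(self.params.alpha / (2.0 * self.W0))

    @property
    def W_L(self) -> float: return float(self.W_out[-1])

    @property
    def J_L(self) -> float: return float(self.J_out[-1])

    @property
    def M_L(self) -> float: return float(self.M_out[-1])

    @property
    def U_L(self) -> float:
        # regularized minus-root limit at W = 0
        return float(self.params.d * self.J_L / self.params.alpha)

    def as_guess(self) -> OuterGuess:
        return OuterGuess(self.z_mesh.copy(), self.W_out.copy(),
                          self.J_out.copy(), self.M_out.copy(), self.L)


def u_out_roots(W, J, p: Params):
    """Both roots of the quadratic closure ``W U**2 - alpha U + d J = 0``.

    Returns ``(u_plus, u_minus)``.  The minus root is evaluated in the
    cancellation-free form ``2 d J / (alpha + sqrt(disc))``, which extends
    continuously to the boundary value ``d J / alpha`` as ``W -> 0``.
    Raises :class:`ComplexRootError` when the discriminant is negative
    (outer-solution breakdown, ``d >= d*``).
    """
    W = np.asarray(W, dtype=float)
    J = np.asarray(J, dtype=float)
    al = p.alpha
    disc = al * al - 4.0 * p.d * J * W
    if np.any(disc < -1e-10 * al * al):
        raise ComplexRootError(
            f"negative discriminant (min {disc.min():.3e}): no real outer "
            "solution; d is at or above the critical dispersal rate")
    root = np.sqrt(np.clip(disc, 0.0, None))
    u_minus = 2.0 * p.d * J / (al + root)
    with np.errstate(divide="ignore"):
        u_plus = np.where(W > 0, (al + root) / (2.0 * np.where(W > 0, W, 1.0)),
                          np.inf)
    return u_plus, u_minus


#: smoothing scale for the positive part of the discriminant inside Newton
#: iterations (the discriminant is O(alpha^2) ~ 1)
_DISC_EPS = 1e-9


def _u_minus_clipped(W, J, p: Params):
    """Minus root with a smoothed positive part of the discriminant.

    Used inside Newton iterations, where intermediate iterates may
    transiently violate the discriminant condition: a hard clip would give
    the root a discontinuous derivative there and stall Newton, so the
    positive part is smoothed on the scale ``1e-9``.  The converged
    solution is re-checked with the strict version.
    """
    al = p.alpha
    disc = al * al - 4.0 * p.d * J * W
    pos = 0.5 * (disc + np.sqrt(disc * disc + _DISC_EPS ** 2))
    return 2.0 * p.d * J / (al + np.sqrt(pos))


def outer_rhs(state, p: Params, *, clip=False):
    """Right-hand side of the outer system for ``(W, J, M)``."""
    W, J, M = state
    u = _u_minus_clipped(W, J, p) if clip else u_out_roots(W, J, p)[1]
    dW = (u * u * W + W - p.a) / p.nu
    return dW, M, p.eta * p.eta * (J - u)


def solve_outer(p: Params, guess: OuterGuess | OuterSolution, *, tol=1e-6,
                max_nodes=20_000) -> OuterSolution:
    """Solve the free-period outer BVP from a guess.

    The guess is typically obtained by stripping the spike from a small-c
    continuation profile (:func:`drylandwaves.scenarios.strip_spike_guess`)
    or from a previously converged :class:`OuterSolution` at nearby
    parameters (bootstrapping).

    The default tolerance reflects the ``sqrt(z)`` behaviour of the minus
    root at ``z = 0`` (the discriminant vanishes there by construction):
    collocation converges to ~1e-7 residual and further refinement only
    chases the corner; the free period is already converged to ~1e-4
    relative at the default tolerance.
    """
    if isinstance(guess, OuterSolution):
        guess = guess.as_guess()
    a, al, d, eta, nu = p.a, p.alpha, p.d, p.eta, p.nu

    def fun(x, y, pars):
        L = pars[0]
        W, J, M = y
        u = _u_minus_clipped(W, J, p)
        return L * np.vstack([(u * u * W + W - a) / nu, M,
                              eta * eta * (J - u)])

    def bc(ya, yb, pars):
        return np.array([
            yb[0] - W_FLOOR,
            ya[0] * ya[1] - al * al / (4.0 * d),
            yb[1] - ya[1],
            yb[2] - (ya[2] + eta * eta * nu * ya[0] / al),
        ])

    s = guess.z / guess.L
    s[0], s[-1] = 0.0, 1.0
    Y = np.vstack([np.clip(guess.W, W_FLOOR, None), guess.J, guess.M])
    sol = solve_bvp(fun, bc, s, Y, p=[guess.L], tol=tol, max_nodes=max_nodes)
    if sol.status != 0:
        raise ConvergenceError(f"outer BVP failed: {sol.message}",
                               residual=float(np.max(sol.rms_residuals)))
    L = float(sol.p[0])
    if L <= 0:
        raise ConvergenceError(f"non-positive period L={L} rejected")
    out = OuterSolution(sol.x * L, *sol.y, L=L, params=p.replace(c=0.0),
                        residual=float(np.max(sol.rms_residuals)))
    # strict real-root check on the converged solution
    disc = al * al - 4.0 * d * out.J_out * out.W_out
    if disc.min() < -1e-10 * al * al:
        raise ComplexRootError(
            f"converged outer iterate violates the discriminant condition "
            f"(min {disc.min():.3e})")
    return out


def discriminant_slope_at_origin(sol: OuterSolution,
                                 p: Params | None = None) -> float:
    """d/dz of ``alpha**2 - 4 d J_out W_out`` at ``z = 0``, analytically.

    Uses the product rule with ``W'`` and ``J'`` taken from the outer
    equations (no finite differences).  A positive slope is necessary for
    the outer solution to exist: the boundary condition pins the
    discriminant to zero at ``z = 0`` and it must be non-negative in the
    interior.  The slope decreases with ``d`` and its zero defines d*.
    """
    p = sol.params if p is None else p
    W0, J0, M0 = sol.W0, sol.J0, sol.M0
    dW0, _, _ = outer_rhs((W0, J0, M0), p, clip=True)
    return float(-4.0 * p.d * (M0 * W0 + J0 * dW0))


def find_dstar(p: Params, d_range, guess: OuterGuess | OuterSolution, *,
               xtol=1e-4, max_step=0.05, tol=1e-6) -> float:
    """Critical dispersal rate d* at fixed ``a, b, nu, eta``.

    Walks ``d`` from the guess's dispersal rate towards and across
    ``d_range`` re-solving the outer BVP at each step (bootstrapped from
    the previous solution; ``alpha = b + d`` updates with ``d``), brackets
    the sign change of :func:`discriminant_slope_at_origin`, and bisects to
    a bracket width ``<= xtol``.  Solver failure or a complex-root error at
    a trial ``d`` is treated as being above d*.
    """
    d_lo, d_hi = sorted(d_range)
    if isinstance(guess, OuterGuess):
        raise DomainError("find_dstar needs a converged OuterSolution guess "
                          "carrying its parameters")
    sols: dict[float, OuterSolution] = {guess.params.d: guess}

    def nearest(d):
        key = min(sols, key=lambda k: abs(k - d))
        return sols[key]

    def solve_at(d):
        """Converged outer solution at d, stepping from the nearest one."""
        if d in sols:
            return sols[d]
        base = nearest(d)
        cur, cur_d = base, base.params.d
        while not math.isclose(cur_d, d, rel_tol=0, abs_tol=1e-12):
            step = float(np.clip(d - cur_d, -max_step, max_step))
            nxt = None
            while nxt is None:
                trial = cur_d + step
                try:
                    nxt = solve_outer(p.replace(d=trial), cur, tol=tol)
                except (ConvergenceError, ComplexRootError):
                    step *= 0.5
                    # a solvable target is reachable with moderate steps;
                    # persistent failure means d is beyond the breakdown
                    if abs(step) < max_step / 128.0:
                        raise
            cur, cur_d = nxt, trial
            sols[round(cur_d, 12)] = cur
        return cur

    def slope(d):
        try:
            sol = solve_at(d)
        except (ConvergenceError, ComplexRootError):
            return None  # treated as d above d*
        return discriminant_slope_at_origin(sol)

    s_lo = slope(d_lo)
    if s_lo is None or s_lo <= 0:
        raise NotFoundError(f"discriminant slope not positive at d={d_lo}; "
                            "bracket does not contain d*")
    s_hi = slope(d_hi)
    if s_hi is not None and s_hi > 0:
        raise NotFoundError(f"discriminant slope still positive at d={d_hi}; "
                            "bracket does not contain d*")
    lo, hi = d_lo, d_hi
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        s_mid = slope(mid)
        logger.info("find_dstar: d=%.6f slope=%s", mid,
                    "fail" if s_mid is None else f"{s_mid:.3e}")
        if s_mid is not None and s_mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
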