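"""End-to-end analysis chains shared by the CLI, tests and scripts.

The package's results all hang off one chain: enter the wave family at the
Hopf bifurcation, continue down in migration speed, strip the spike to
bootstrap the zero-speed outer problem, resolve the matching constants and
assemble composites.  These helpers wire the stages together with the
reference study parameters.
"""

from __future__ import annotations

import numpy as np

from .layers import CompositeSolution, compose, matching_constants
from .model import Params
from .outer import OuterSolution, solve_outer
from .scenarios import paper_params, strip_spike_guess
from .waves import Branch, WaveProfile, continue_branch, enter_branch

__all__ = ["speed_branch", "profile_at_c", "outer_reference",
           "composite_at", "rainfall_sweep_outer", "rainfall_sweep_waves"]


def speed_branch(targets=(0.1, 0.01, 0.001, 0.0001), params: Params | None
                 = None, *, keep_intermediate=True, tol=1e-6) -> Branch:
    """Wave branch through a decreasing schedule of migration speeds.

    Enters at the Hopf bifurcation with ``c = targets[0]``, continues the
    rainfall to the requested value, then continues down in ``c`` through
    every target.
    """
    p = params if params is not None else paper_params("fig2").params
    start = enter_branch(p, c=targets[0], tol=tol)
    return continue_branch(start, "c", list(targets), tol=tol,
                           keep_intermediate=keep_intermediate)


def profile_at_c(branch: Branch, c: float) -> WaveProfile:
    """The branch profile at speed ``c`` (exact match required)."""
    for prof in branch.profiles:
        if np.isclose(prof.c, c, rtol=1e-12):
            return prof
    raise KeyError(f"no profile at c={c} on the branch")


def outer_reference(source, params: Params | None = None, *,
                    tol=1e-6) -> OuterSolution:
    """Outer solution bootstrapped from a wave profile or branch.

    ``source`` may be a :class:`WaveProfile` (typically ``c = 1e-3``) or a
    :class:`Branch`, in which case the profile with speed closest to
    ``c = 1e-3`` is used.
    """
    if isinstance(source, Branch):
        source = min(source.profiles, key=lambda q: abs(q.c - 1e-3))
    p = source.params.replace(c=0.0) if params is None else params
    return solve_outer(p, strip_spike_guess(source), tol=tol)


def composite_at(outer_sol: OuterSolution, c: float, *, gauge="peak",
                 **kw) -> CompositeSolution:
    """Composite solution of one period at migration speed ``c``."""
    k = matching_constants(outer_sol)
    return compose(outer_sol, k, c=c, gauge=gauge, **kw)


def rainfall_sweep_outer(outer0: OuterSolution, a_values, *, max_step=0.02,
                         tol=1e-6) -> list[OuterSolution]:
    """Re-solve the outer problem along a rainfall schedule (bootstrapped)."""
    sols = []
    cur = outer0
    for a in a_values:
        val = cur.params.a
        while abs(val - a) > 1e-12:
            step = float(np.clip(a - val, -max_step, max_step))
            while True:
                try:
                    nxt = solve_outer(cur.params.replace(a=val + step), cur,
                                      tol=tol)
                    break
                except Exception:
                    step *= 0.5
                    if abs(step) < 1e-7:
                        raise
            cur, val = nxt, val + step
        sols.append(cur)
    return sols


def rainfall_sweep_waves(start: WaveProfile, a_values, *,
                         tol=1e-6) -> Branch:
    """Continue the wave branch in rainfall at fixed speed."""
    lo = [a for a in a_values if a < start.params.a]
    hi = [a for a in a_values if a >= start.params.a]
    branch = Branch(param_name="a", profiles=[])
    if lo:
        down = continue_branch(start, "a", sorted(lo, reverse=True), tol=tol)
        branch.profiles.extend(down.profiles[::-1])
        branch.complete &= down.complete
    if hi:
        up = continue_branch(start, "a", sorted(hi), tol=tol)
        branch.profiles.extend(up.profiles)
        branch.complete &= up.complete
    return branch
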