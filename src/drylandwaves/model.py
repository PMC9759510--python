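"""Model definitions for the Klausmeier system with long-range seed dispersal.

The model couples water ``w`` and plant biomass ``u`` on a uniform slope.
Water is supplied at rate ``a`` (proportional to mean annual rainfall),
evaporates linearly, is taken up by plants at rate ``u**2 * w`` and flows
downhill with advection speed ``nu``.  Plants grow at the water-uptake rate,
die at per-capita rate ``b`` and disperse seeds non-locally: the dispersal
term is ``d * (phi * u - u)`` with ``phi`` a Laplace (two-sided exponential)
kernel of inverse width ``eta``.  Because the Laplace kernel is the Green's
function of ``1 - eta**-2 * d2/dx2``, the convolution ``j = phi * u``
satisfies ``j'' + eta**2 (u - j) = 0`` and the integro-PDE reduces to a local
three-field system; that identity underpins every other module.

This module holds the parameter container, the non-spatial kinetics and
steady states, the kernel and its Fourier multiplier, linear dispersion
about a uniform state, and classification of initial states into the basins
of attraction of the vegetated / unvegetated equilibria.
"""

from __future__ import annotations

import configparser
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from ._errors import DomainError, ParameterError, ShapeError

__all__ = [
    "Params",
    "UniformState",
    "uniform_steady_states",
    "nonspatial_rhs",
    "classify_basin",
    "laplace_kernel",
    "kernel_multiplier",
    "linear_dispersion",
    "convolution_residual",
]


@dataclass(frozen=True)
class Params:
    """Dimensionless parameters of the nonlocal vegetation model.

    Attributes
    ----------
    a : float
        Rainfall parameter (> 0).
    b : float
        Plant loss rate (> 0).
    nu : float
        Slope-induced water advection speed (>= 0).
    d : float
        Seed dispersal rate (> 0).
    eta : float
        Inverse width of the Laplace dispersal kernel (> 0).
    c : float
        Uphill migration speed of the pattern (>= 0).  ``c`` is a property
        of a particular travelling-wave solution rather than of the model,
        but carrying it here keeps every equation's symbols in one place.
    alpha : float
        Derived: ``alpha = b + d``.  Set automatically.
    """

    a: float
    b: float
    nu: float
    d: float
    eta: float
    c: float = 0.0
    alpha: float = field(init=False)

    def __post_init__(self):
        for name in ("a", "b", "d", "eta"):
            if not getattr(self, name) > 0.0:
                raise ParameterError(f"{name} must be strictly positive")
        for name in ("nu", "c"):
            if getattr(self, name) < 0.0:
                raise ParameterError(f"{name} must be non-negative")
        object.__setattr__(self, "alpha", self.b + self.d)

    def replace(self, **kwargs) -> "Params":
        """Return a copy with some fields replaced (alpha re-derived)."""
        current = dict(a=self.a, b=self.b, nu=self.nu, d=self.d,
                       eta=self.eta, c=self.c)
        current.update(kwargs)
        return Params(**current)

    # -- serialization ----------------------------------------------------
    _KEYS = ("a", "b", "nu", "d", "eta", "c")

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self._KEYS}

    @classmethod
    def from_dict(cls, mapping) -> "Params":
        unknown = set(mapping) - set(cls._KEYS)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_file(self, path) -> None:
        """Write a flat key-value config (JSON if suffix is .json, else INI)."""
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            cp = configparser.ConfigParser()
            cp["params"] = {k: repr(v) for k, v in self.to_dict().items()}
            with open(path, "w") as fh:
                cp.write(fh)

    @classmethod
    def from_file(cls, path) -> "Params":
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json" or text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        cp = configparser.ConfigParser()
        cp.read_string(text)
        section = cp["params"] if cp.has_section("params") else cp[cp.sections()[0]]
        return cls.from_dict({k: float(v) for k, v in section.items()})


@dataclass(frozen=True)
class UniformState:
    """A spatially uniform steady state of the non-spatial kinetics."""

    w: float
    u: float
    stability_label: str  # one of {"stable", "unstable", "saddle"}


def nonspatial_rhs(w, u, p: Params):
    """Kinetics with all spatial terms removed.

    For spatially uniform fields the dispersal convolution returns the field
    itself (the kernel integrates to one), so ``j == u`` and the dispersal
    term vanishes identically; the reduced kinetics coincide with the local
    model's.
    """
    dw = p.a - w - u * u * w
    du = u * u * w - p.b * u
    return dw, du


def _nonspatial_jacobian(w, u, p: Params):
    return np.array([
        [-1.0 - u * u, -2.0 * u * w],
        [u * u, 2.0 * u * w - p.b],
    ])


def _label_from_jacobian(w, u, p: Params) -> str:
    eigs = np.linalg.eigvals(_nonspatial_jacobian(w, u, p))
    re = eigs.real
    if np.all(re < 0):
        return "stable"
    if np.isrealobj(eigs) or np.all(np.abs(eigs.imag) < 1e-12):
        if re.min() < 0 < re.max():
            return "saddle"
    return "unstable"


def uniform_steady_states(p: Params) -> list[UniformState]:
    """All uniform steady states, bare state first.

    The bare-soil state ``(w, u) = (a, 0)`` always exists.  Vegetated states
    solve ``b u**2 - a u + b = 0`` with ``w = b / u``; they exist iff
    ``a >= 2 b`` (a double root exactly at ``a = 2 b``).
    """
    states = [UniformState(p.a, 0.0, _label_from_jacobian(p.a, 0.0, p))]
    disc = p.a * p.a - 4.0 * p.b * p.b
    if disc < 0.0:
        return states
    roots = sorted({(p.a - math.sqrt(disc)) / (2.0 * p.b),
                    (p.a + math.sqrt(disc)) / (2.0 * p.b)})
    for u in roots:
        w = p.b / u
        states.append(UniformState(w, u, _label_from_jacobian(w, u, p)))
    return states


def vegetated_state(p: Params) -> UniformState:
    """The vegetated state that is stable to homogeneous perturbations.

    This is the larger-``u`` root; the label is verified from the Jacobian
    rather than assumed.
    """
    states = [s for s in uniform_steady_states(p) if s.u > 0]
    if not states:
        raise DomainError("no vegetated steady state exists (a < 2b)")
    best = max(states, key=lambda s: s.u)
    return best


def classify_basin(w, u, p: Params, *, t_max=1000.0, rtol=1e-8,
                   reach_tol=1e-5) -> str:
    """Classify an initial state into a basin of attraction.

    Forward-integrates the non-spatial kinetics and reports which stable
    steady state (vegetated -> ``"veg"``, bare -> ``"no_veg"``) is reached
    within ``reach_tol``; ``"boundary"`` if neither is approached by
    ``t_max`` (the initial state lies near the separatrix through the
    saddle).
    """
    if w < 0 or u < 0:
        raise DomainError("w and u must be non-negative")
    states = uniform_steady_states(p)
    stable = [s for s in states if s.stability_label == "stable"]
    veg = [s for s in stable if s.u > 0]
    if not veg:
        raise DomainError("no vegetated attractor exists for these parameters")
    targets = {"no_veg": (p.a, 0.0), "veg": (veg[0].w, veg[0].u)}

    def rhs(t, y):
        return nonspatial_rhs(y[0], y[1], p)

    def events(label):
        wt, ut = targets[label]

        def ev(t, y):
            return math.hypot(y[0] - wt, y[1] - ut) - reach_tol
        ev.terminal = True
        ev.direction = -1
        return ev

    evs = [events("no_veg"), events("veg")]
    sol = solve_ivp(rhs, (0.0, t_max), [w, u], rtol=rtol, atol=1e-10,
                    events=evs, method="LSODA")
    if sol.t_events[0].size:
        return "no_veg"
    if sol.t_events[1].size:
        return "veg"
    # no event fired: check the final point anyway, else boundary
    wf, uf = sol.y[:, -1]
    for label, (wt, ut) in targets.items():
        if math.hypot(wf - wt, uf - ut) <= reach_tol:
            return label
    return "boundary"


def laplace_kernel(xi, eta):
    """Laplace (two-sided exponential) dispersal kernel.

    ``phi(xi) = eta/2 * exp(-eta |xi|)``; symmetric, unit mass.
    """
    if not eta > 0:
        raise ParameterError("eta must be strictly positive")
    return 0.5 * eta * np.exp(-eta * np.abs(xi))


def kernel_multiplier(k, eta, d):
    """Fourier multiplier of the dispersal operator ``d (phi * u - u)``.

    The Laplace kernel transforms to ``eta**2 / (eta**2 + k**2)``, so the
    operator acts on mode ``exp(i k x)`` as multiplication by
    ``-d k**2 / (eta**2 + k**2)``: zero mass-loss at ``k = 0``, saturating
    at ``-d`` for short-wavelength modes (unlike diffusion, non-local
    dispersal cannot damp arbitrarily fast).
    """
    if not eta > 0:
        raise ParameterError("eta must be strictly positive")
    k = np.asarray(k, dtype=float)
    return -d * k * k / (eta * eta + k * k)


def linear_dispersion(p: Params, k, *, state: UniformState | None = None,
                      local: bool = False):
    """Eigenvalues of the linearization about a uniform state at wavenumber k.

    The water row gains ``+ i nu k`` from advection; the plant row gains the
    dispersal multiplier (``kernel_multiplier`` for the nonlocal model,
    ``-k**2`` for the local diffusion model).  Returns the two eigenvalues
    of the 2x2 Fourier-mode matrix, sorted by descending real part.
    """
    if state is None:
        state = vegetated_state(p)
    J = _nonspatial_jacobian(state.w, state.u, p).astype(complex)
    J[0, 0] += 1j * p.nu * k
    J[1, 1] += (-k * k) if local else kernel_multiplier(k, p.eta, p.d)
    eigs = np.linalg.eigvals(J)
    return eigs[np.argsort(-eigs.real)]


def convolution_residual(u_field, j_field, eta, dx):
    """Max-norm residual of the reduction identity ``j'' + eta^2 (u - j) = 0``.

    ``j_field`` should be the discrete periodic convolution of ``u_field``
    with the Laplace kernel; the residual then vanishes as ``O(dx**2)``.
    Uses a centred second difference with periodic wrap.
    """
    u = np.asarray(u_field, dtype=float)
    j = np.asarray(j_field, dtype=float)
    if u.shape != j.shape or u.ndim != 1:
        raise ShapeError("u_field and j_field must be 1-D arrays of equal length")
    jpp = (np.roll(j, -1) - 2.0 * j + np.roll(j, 1)) / (dx * dx)
    return float(np.max(np.abs(jpp + eta * eta * (u - j))))


def periodic_convolve(u_field, eta, dx):
    """Discrete periodic convolution of a field with the Laplace kernel.

    The kernel is truncated at ``|xi| <= 40 / eta`` (tail below 1e-17) and
    wrapped onto the periodic grid; the discrete kernel is renormalized to
    unit mass so that constants are preserved exactly.
    """
    u = np.asarray(u_field, dtype=float)
    n = u.size
    half = min(int(math.ceil(40.0 / (eta * dx))), 20 * n)
    offsets = np.arange(-half, half + 1)
    weights = laplace_kernel(offsets * dx, eta) * dx
    weights /= weights.sum()
    kernel = np.zeros(n)
    np.add.at(kernel, np.mod(offsets, n), weights)
    return np.real(np.fft.ifft(np.fft.fft(u) * np.fft.fft(kernel)))
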