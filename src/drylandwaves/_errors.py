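"""Exception hierarchy shared across the package."""


class DrylandWavesError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DrylandWavesError, ValueError):
    """Invalid or inconsistent model parameters."""


class DomainError(DrylandWavesError, ValueError):
    """An operation was called outside its domain of validity."""


class ShapeError(DrylandWavesError, ValueError):
    """Array arguments with incompatible shapes or grids."""


class ConvergenceError(DrylandWavesError, RuntimeError):
    """An iterative solver failed to converge.

    Attributes
    ----------
    residual : float or None
        Last residual reported by the solver, if available.
    """

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class ComplexRootError(DrylandWavesError, ArithmeticError):
    """The outer quadratic closure has a negative discriminant.

    Signals breakdown of the outer solution structure (d at or above the
    critical dispersal rate d*).
    """


class NotFoundError(DrylandWavesError, RuntimeError):
    """A bracketed search (Hopf locus, d*) found no crossing in range."""
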