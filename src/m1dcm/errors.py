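"""Exception hierarchy shared across the package."""


class M1DCMError(Exception):
    """Base class for all package-specific errors."""


class InvalidArchitectureError(M1DCMError, ValueError):
    """A model specification violates an architecture-family constraint."""


class ParameterError(M1DCMError, ValueError):
    """A parameter value is outside its admissible range."""


class ShapeError(M1DCMError, ValueError):
    """Array dimensions are inconsistent with the model."""


class NumericalError(M1DCMError, FloatingPointError):
    """A state or intermediate quantity became non-finite."""


class InstabilityError(M1DCMError, RuntimeError):
    """Time-domain simulation diverged beyond the configured bound."""


class StabilityError(M1DCMError, RuntimeError):
    """The linearised system has eigenvalues with non-negative real part."""


class DelayError(M1DCMError, RuntimeError):
    """The first-order delay correction is singular."""


class FixedPointError(M1DCMError, RuntimeError):
    """Root finding for the network equilibrium did not converge."""


class BandError(M1DCMError, ValueError):
    """Requested frequencies lie outside the modelled 5-45 Hz band."""


class GridMismatchError(M1DCMError, ValueError):
    """Data and prediction are defined on different frequency grids."""


class DesignError(M1DCMError, ValueError):
    """A condition label or modulation design is invalid for the model."""


class IncompleteGridError(M1DCMError, ValueError):
    """The subjects-by-models free-energy grid has missing cells."""
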