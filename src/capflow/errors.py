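"""Exception hierarchy.

Everything derives from :class:`CapflowError` so callers can catch the
package's failures with one clause; most errors are also ``ValueError``
subclasses because they signal invalid inputs.
"""


class CapflowError(Exception):
    """Base class for all capflow errors."""


class InvalidGeometryError(CapflowError, ValueError):
    """Capillary cross-section axes are inconsistent or non-positive."""


class InvalidFluidError(CapflowError, ValueError):
    """Fluid properties violate their physical invariants."""


class InvalidDeviceError(CapflowError, ValueError):
    """Device configuration violates its geometric invariants."""


class InvalidObservationError(CapflowError, ValueError):
    """An observed quantity (e.g. equilibrium height) is out of range."""


class SingularInputError(CapflowError, ValueError):
    """Model evaluated at a point where it is singular (H = 0, no loop)."""


class UnreachableHeightError(CapflowError, ValueError):
    """Target height at or above equilibrium / device extent."""


class StalledFrontError(CapflowError, ValueError):
    """Liquid front cannot traverse the loop (entry at/above equilibrium)."""


class InvalidScheduleError(CapflowError, ValueError):
    """Sampling times are not strictly increasing or start below zero."""


class InvalidTrajectoryError(CapflowError, ValueError):
    """Trajectory samples violate the timeseries invariants."""


class DegenerateDataError(CapflowError, ValueError):
    """Group statistics requested on degenerate data (no within-group variance)."""


class UnfittableProfileError(CapflowError, ValueError):
    """Too few usable velocity points below equilibrium to fit."""


class InvalidProfileError(CapflowError, ValueError):
    """Stimulation profile implies a non-positive viscosity."""


class ConfigError(CapflowError, ValueError):
    """Experiment configuration failed schema validation."""
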