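"""Exception taxonomy for the measurement pipeline.

Every stage raises a subclass of :class:`ProxhumError` so callers (and the
CLI) can distinguish bad geometry from bad files from bad tables.
"""


class ProxhumError(Exception):
    """Base class for all package errors."""


class DegenerateGeometryError(ProxhumError, ValueError):
    """Collinear/coincident points, parallel planes, zero-length vectors."""


class CylinderFitError(ProxhumError, ValueError):
    """Insufficient or degenerate point sets for the shaft-cylinder fit."""


class ConvergenceError(ProxhumError, RuntimeError):
    """Iterative fit did not converge; carries the last iterate.

    Attributes
    ----------
    last_iterate : object
        The best parameters found before giving up.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class MissingRegionError(ProxhumError, ValueError):
    """A labelled vertex region required by a measurement is empty."""


class NoIntersectionError(ProxhumError, ValueError):
    """A constructed line/plane does not meet the surface it must cross."""


class OrientationError(ProxhumError, ValueError):
    """A plane/axis orientation convention is violated by the input."""


class FormatError(ProxhumError, ValueError):
    """Unreadable or unsupported mesh/annotation file."""


class SchemaError(ProxhumError, ValueError):
    """A cohort/measurement table is missing required columns or cells."""


class ValidationError(ProxhumError, ValueError):
    """Invalid generator or configuration parameters; lists all violations."""

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))
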