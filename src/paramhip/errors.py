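"""Exception hierarchy for paramhip.

All geometry/physics precondition violations raise :class:`DomainError` (a
``ValueError``) so that callers can catch a single type; more specific
subclasses exist where the failure mode is actionable.
"""


class ParamhipError(Exception):
    """Base class for all paramhip errors."""


class DomainError(ParamhipError, ValueError):
    """An input violates a documented precondition (range, sign, geometry)."""


class SingularConfigurationError(DomainError):
    """Degenerate point configuration for a primitive fit (coplanar sphere
    points, collinear plane/circle points)."""


class LabelledInputError(DomainError):
    """A labelled surface is missing a required region label."""


class FormatError(ParamhipError, ValueError):
    """A file does not conform to the expected schema (CSV columns, YAML keys)."""


class SolverError(ParamhipError, RuntimeError):
    """The contact equilibrium iteration failed to converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoEquilibriumError(SolverError):
    """The load direction has no cartilage support (edge-of-coverage
    dislocation): no static equilibrium exists within the cartilage layer."""
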