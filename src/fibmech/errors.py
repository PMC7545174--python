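"""Exception hierarchy.

All user-facing failures derive from :class:`FibmechError` so callers can
catch package errors with one clause; subclasses also inherit the closest
builtin (ValueError and friends) so idiomatic handling keeps working.
"""


class FibmechError(Exception):
    """Base class for all package errors."""


class ValidationError(FibmechError, ValueError):
    """Invalid input data or parameters."""


class ConfigurationError(FibmechError, ValueError):
    """Inconsistent or unstable configuration (e.g. integrator timestep)."""


class RangeError(FibmechError, ValueError):
    """Requested point lies outside a profile's domain."""


class DegenerateGeometryError(FibmechError, ValueError):
    """Geometry does not admit the requested metric (zero-length vectors)."""


class DataInconsistencyError(FibmechError, ValueError):
    """A record contradicts the domain annotation it is checked against."""
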