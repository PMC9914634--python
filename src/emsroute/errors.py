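"""Exception hierarchy shared across the package.

Every error raised inside the four-phase dispatch pipeline carries the
phase name in its message so operators can see where a request failed.
"""


class EmsRouteError(Exception):
    """Base class for all package errors."""


class FormatError(EmsRouteError):
    """A file could not be parsed under the declared dialect."""


class NetworkValidationError(EmsRouteError):
    """A record violates a road-network invariant (e.g. zero-length edge)."""


class DomainError(EmsRouteError, ValueError):
    """A scalar input is outside the formula's domain (e.g. speed <= 0)."""


class NoCoverageError(EmsRouteError):
    """A demand node lies in a component containing no facility."""


class ExhaustionError(EmsRouteError):
    """No available facility exists anywhere in the catchment adjacency graph."""
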