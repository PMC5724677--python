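"""Exception hierarchy shared across the package.

All errors derive from :class:`TaufluxError` so callers can catch one base
class; most also derive from :class:`ValueError` because they signal invalid
or degenerate inputs rather than programming faults.
"""


class TaufluxError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(TaufluxError, ValueError):
    """An input violates a documented precondition."""


class DegenerateDesignError(TaufluxError, ValueError):
    """A regression design has no spread (e.g. a single concentration level)."""


class InternalStandardFailureError(TaufluxError, ValueError):
    """The internal-standard response is missing or non-positive (lost IS)."""


class LimitsNotReachedError(TaufluxError, ValueError):
    """No dilution level reaches the required signal-to-noise threshold."""


class MissingFactorError(TaufluxError, KeyError):
    """No carbon-conversion factor is configured for a taxon group."""


class InsufficientPointsError(TaufluxError, ValueError):
    """Fewer than three usable time points remain for a rate regression."""


class UndefinedStatisticError(TaufluxError, ValueError):
    """A statistic is undefined for the given data (zero mean, zero spread...)."""


class PairingError(TaufluxError, ValueError):
    """A sample/control pair does not match (different analyte or grid)."""


class MissingDataError(TaufluxError, ValueError):
    """A required observation (depth window, N species, group) is absent."""
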