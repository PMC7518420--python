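"""Exception hierarchy shared across the package."""


class MucoscapeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MucoscapeError, ValueError):
    """A parameter value is out of range or inconsistent; names the field."""


class ConfigurationError(MucoscapeError, ValueError):
    """A required channel, mapping, or config entry is missing."""


class ValidationError(MucoscapeError, ValueError):
    """A record or data structure violates its contract."""


class EmptyCompartmentError(MucoscapeError, ValueError):
    """A mask or contour is empty; dependent statistics are undefined."""


class UndefinedStatisticError(MucoscapeError, ValueError):
    """A statistic was requested over an empty support."""


class DegenerateDataError(MucoscapeError, ValueError):
    """Input data cannot constrain the model (e.g. constant response)."""
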