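"""Exception hierarchy shared across the package."""


class CryptDynError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CryptDynError, ValueError):
    """A numeric parameter is negative, non-finite or otherwise invalid."""


class CalibrationError(CryptDynError):
    """An operation required the LOH constant alpha before it was calibrated."""


class ConfigurationError(CryptDynError):
    """A gene, scenario or matrix configuration is inconsistent."""


class QueryError(CryptDynError, KeyError):
    """An aggregation query referenced an unknown state or gene."""


class AlignmentError(CryptDynError):
    """Two trajectories cannot be compared (age grids differ)."""


class NumericalError(CryptDynError):
    """The solver produced non-finite or significantly negative values."""
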