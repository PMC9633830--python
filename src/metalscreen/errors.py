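"""Exception hierarchy.

All package errors derive from :class:`MetalScreenError` so callers can
catch everything with one clause; the three subclasses map onto the CLI
exit codes (config -> 2, data -> 3).
"""


class MetalScreenError(Exception):
    """Base class for all errors raised by metalscreen."""


class ConfigurationError(MetalScreenError):
    """Invalid configuration: bad scheme name, degenerate bbox, rho outside [-1, 1], ..."""


class DataError(MetalScreenError):
    """Invalid data: negative concentrations, empty groups, constant blanks, ..."""


class NumericalError(MetalScreenError):
    """Numerical failure, e.g. a covariance matrix that is not positive definite
    even after nugget jitter."""
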