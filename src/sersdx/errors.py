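"""Exception hierarchy shared by all sersdx modules."""


class SersdxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SersdxError):
    """Invalid generator / pipeline configuration (bad axis, missing keys...)."""


class ParameterError(SersdxError):
    """An operation was called with out-of-contract parameters."""


class DataError(SersdxError):
    """Input data violates the operation's preconditions."""


class DegenerateInputError(DataError):
    """Input is formally valid but degenerate (e.g. constant spectrum for SNV)."""


class FitError(SersdxError):
    """Model fitting failed (rank deficiency, single-class response...)."""


class MetricError(SersdxError):
    """A classification metric is undefined for the given truth/score vectors."""
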