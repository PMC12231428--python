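"""Exception hierarchy for ecpredict.

All package errors derive from :class:`EcpredictError`; the argument- and
schema-related ones also derive from ``ValueError`` so generic callers that
catch ``ValueError`` keep working.
"""


class EcpredictError(Exception):
    """Base class for all ecpredict errors."""


class ConfigError(EcpredictError, ValueError):
    """Invalid argument or configuration value."""


class SchemaError(EcpredictError, ValueError):
    """Malformed tabular input (atlas, phenotype or time-series tables)."""


class StabilityError(EcpredictError):
    """A connectivity matrix could not be stabilised (spectral abscissa >= 0)."""


class DegenerateInputError(EcpredictError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant signal)."""


class NumericalError(EcpredictError):
    """Non-finite values encountered during iterative estimation."""
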