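"""Exception hierarchy for nirclda.

All package errors derive from :class:`NirCldaError` so callers can catch
everything the library raises with a single except clause.
"""


class NirCldaError(Exception):
    """Base class for all nirclda errors."""


class ParseError(NirCldaError):
    """A delimited-text spectral file could not be parsed."""


class SchemaError(NirCldaError):
    """Input data violates the expected schema (missing labels, bad shapes)."""


class ConfigError(NirCldaError):
    """An invalid configuration or specification was supplied."""


class ParameterError(NirCldaError, ValueError):
    """An operation received an out-of-range parameter."""


class DegenerateDataError(NirCldaError):
    """Data is degenerate for the requested operation (e.g. constant spectrum,
    coinciding common vectors, zero-variance MSC reference)."""


class RegimeError(NirCldaError):
    """The data is outside the small-sample regime the method requires."""


class FitError(NirCldaError):
    """Model fitting failed (e.g. the first boosting round is degenerate)."""
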