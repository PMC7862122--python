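"""Exception hierarchy.

Validation errors (bad records, malformed thresholds, inconsistent counts)
and configuration errors are distinguished from ordinary input errors so
the CLI can map them onto distinct exit codes.
"""


class HerbnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HerbnetError):
    """A simulation or pipeline configuration violates its invariants."""


class ValidationError(HerbnetError):
    """A record or parameter fails a well-formedness check."""


class InputError(HerbnetError):
    """An input table or file is unusable (empty, missing columns, ...)."""
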