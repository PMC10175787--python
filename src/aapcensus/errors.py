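"""Exception hierarchy shared across the pipeline stages."""


class AAPCensusError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(AAPCensusError):
    """A configuration value is missing, inconsistent, or names an unknown entity."""


class FormatError(AAPCensusError):
    """An input file violates its declared dialect (bad column, value, or vocabulary)."""


class UsageError(AAPCensusError):
    """An operation was called with arguments violating its contract."""
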