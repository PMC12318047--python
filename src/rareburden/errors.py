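"""Exception types shared across the package."""


class RareBurdenError(Exception):
    """Base class for all package errors."""


class DataError(RareBurdenError, ValueError):
    """A record, table or file violates the data contract."""


class ConfigError(RareBurdenError, ValueError):
    """A configuration value is invalid; the message names the offending field."""
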