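"""Exception hierarchy."""


class PribinError(Exception):
    """Base class for all package errors."""


class FcsFormatError(PribinError):
    """Malformed or unsupported FCS file content."""


class ConfigError(PribinError):
    """Invalid configuration (unknown marker, bad interval, bad threshold...)."""


class StateError(PribinError):
    """Operation applied to an object in the wrong state (e.g. double transform)."""
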