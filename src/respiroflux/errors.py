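"""Exception hierarchy shared across the pipeline stages."""


class RespirofluxError(Exception):
    """Base class for all package errors."""


class FormatError(RespirofluxError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class DataError(RespirofluxError):
    """A file parses but its content violates a data invariant."""


class ConfigError(RespirofluxError):
    """Invalid configuration (inconsistent effect table, bad parameter)."""


class DerivationError(RespirofluxError):
    """A bioenergetic parameter cannot be derived (e.g. empty phase)."""
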