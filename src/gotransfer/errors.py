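"""Exception hierarchy shared across the package."""


class GoTransferError(Exception):
    """Base class for all errors raised by gotransfer."""


class ParseError(GoTransferError):
    """An input file violates its declared dialect."""


class ValidationError(GoTransferError):
    """Data violates a structural invariant (cycles, dimension mismatch, ...)."""


class UnknownTermError(GoTransferError, KeyError):
    """A GO identifier is not present in the ontology."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return Exception.__str__(self)


class ConfigError(GoTransferError):
    """A configuration value is out of range or unknown."""
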