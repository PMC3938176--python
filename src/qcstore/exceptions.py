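"""Exception hierarchy for qcstore."""


class QCStoreError(Exception):
    """Base class for all qcstore errors."""


class ValidationError(QCStoreError, ValueError):
    """Invalid input to the in-memory analysis builder."""


class ScopeError(ValidationError):
    """A metric key was used with a container that does not match its scope."""


class RangeError(ValidationError):
    """A base-position range is malformed."""


class ParseError(QCStoreError):
    """A report or metadata file could not be parsed.

    Carries the offending path and, where known, the 1-based line number.
    """

    def __init__(self, message, path=None, line=None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(f"{message}{loc}")


class ConfigError(QCStoreError):
    """A connection/config file is missing or malformed."""


class StoreClosedError(QCStoreError):
    """Operation attempted on a disconnected store."""
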