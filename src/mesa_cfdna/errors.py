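"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ``UsageError`` -> 2, ``DataError`` -> 3.
"""


class MesaError(Exception):
    """Base class for all package errors."""


class UsageError(MesaError):
    """Invalid parameters or malformed configuration."""


class ValidationError(UsageError):
    """Input values violate a documented invariant."""


class DataError(MesaError):
    """Input files are missing, malformed, or internally inconsistent."""


class ParseError(DataError):
    """A record could not be parsed; carries file and line context."""

    def __init__(self, message: str, path=None, line: int | None = None):
        ctx = ""
        if path is not None:
            ctx += f" [{path}"
            if line is not None:
                ctx += f":{line}"
            ctx += "]"
        super().__init__(message + ctx)
        self.path = path
        self.line = line
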