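"""Exception hierarchy shared across the package."""


class FibromodError(Exception):
    """Base class for all errors raised by fibromod."""


class ConfigError(FibromodError):
    """A configuration value violates a documented bound."""


class ParseError(FibromodError):
    """A file could not be parsed; carries the offending location.

    Parameters
    ----------
    message : str
        Human-readable description of the problem.
    path : str, optional
        File being parsed.
    line : int, optional
        1-based line number of the offending record.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
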