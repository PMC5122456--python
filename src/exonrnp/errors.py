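"""Exception types shared across the package."""


class ExonRnpError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ExonRnpError):
    """A simulation or pipeline configuration is invalid.

    The message names the offending field.
    """


class NoAnchorError(ExonRnpError):
    """No anchor proteins were found in a ratio table; normalization is impossible."""


class GenerationError(ExonRnpError):
    """A synthetic cohort could not be generated under the requested geometry."""


class ParseError(ExonRnpError):
    """A malformed input file; carries file and line context."""

    def __init__(self, message: str, path=None, line: int | None = None):
        ctx = ""
        if path is not None:
            ctx = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + ctx)
        self.path = path
        self.line = line
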