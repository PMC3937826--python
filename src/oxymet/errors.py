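"""Exception hierarchy shared by all oxymet modules."""


class OxymetError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(OxymetError):
    """A file does not conform to the expected dialect (missing columns, bad layout)."""


class ParseError(FormatError):
    """A single line could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line_no: int | None = None):
        self.path = path
        self.line_no = line_no
        prefix = ""
        if path is not None:
            prefix += f"{path}:"
        if line_no is not None:
            prefix += f"{line_no}: "
        super().__init__(prefix + message)


class ValidationError(OxymetError):
    """Input is syntactically fine but violates a semantic contract."""
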