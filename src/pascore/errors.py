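"""Exception hierarchy shared across the package."""


class PascoreError(Exception):
    """Base class for all package errors."""


class ParseError(PascoreError):
    """A file could not be parsed; the message names the file and line."""


class ValidationError(PascoreError):
    """A parsed object violates a model invariant."""
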