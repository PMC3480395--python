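"""Exception hierarchy shared by all drsn modules."""


class DrsnError(Exception):
    """Base class for all drsn errors."""


class ParseError(DrsnError):
    """A file could not be parsed under its declared dialect."""


class ValidationError(DrsnError):
    """Parsed data violates a structural invariant."""
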