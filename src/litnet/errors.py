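"""Exception types shared across litnet modules."""


class LitnetError(Exception):
    """Base class for all litnet errors."""


class ParseError(LitnetError):
    """A file could not be parsed; the message names the offending line/record."""


class ValidationError(LitnetError):
    """Parsed data violates an invariant (duplicate ids, bad category, ...)."""
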