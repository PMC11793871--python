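"""Exception types raised by the screen-scoring pipeline."""


class ScreenError(Exception):
    """Base class for all pipeline errors."""


class ParseError(ScreenError):
    """A tabular input file could not be parsed or violated its schema."""


class ValidationError(ScreenError):
    """Inputs parsed cleanly but violate a domain invariant."""
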