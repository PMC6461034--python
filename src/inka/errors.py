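"""Exception types shared across the package."""


class InkaError(Exception):
    """Base class for all errors raised by this package."""


class InputFormatError(InkaError):
    """A required column is missing or a cell cannot be interpreted."""
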