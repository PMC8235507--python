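"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter violates an operation's precondition."""


class FormatError(ValueError):
    """An input file is malformed; the message names the offending record/line."""
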