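"""Shared exception types."""


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


class InputError(ValueError):
    """In-memory inputs violate an operation's preconditions."""
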