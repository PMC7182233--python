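"""Exception hierarchy for facsboot."""


class FacsbootError(Exception):
    """Base class for all facsboot errors."""


class ParseError(FacsbootError):
    """A table could not be parsed; the message names the offending line."""


class ValidationError(FacsbootError):
    """Input violated a structural invariant (overlap, bounds, unknown code)."""


class EmptyInputError(FacsbootError):
    """A computation received no usable rows (e.g. zero visible frames)."""
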