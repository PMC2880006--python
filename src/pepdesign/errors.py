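"""Exception types shared across the package."""


class PepDesignError(Exception):
    """Base class for all package-specific errors."""


class InputError(PepDesignError, ValueError):
    """Invalid, incomplete or inconsistent user input."""


class ParseError(PepDesignError, ValueError):
    """A file could not be parsed; the message carries location detail."""


class DegenerateModelError(PepDesignError, RuntimeError):
    """The model admits no viable sequence (e.g. every path has zero probability)."""
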