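"""Exception types shared across the package."""


class LandgenError(Exception):
    """Base class for all package errors."""


class ParseError(LandgenError, ValueError):
    """A file could not be parsed; the message names the offending line/record."""


class ValidationError(LandgenError, ValueError):
    """An object violates a domain invariant; the message names the record."""


class DegenerateDataError(LandgenError, ValueError):
    """The data admit no defined estimate (e.g. zero denominator in a ratio estimator)."""
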