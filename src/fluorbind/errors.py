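"""Exception hierarchy shared by all fluorbind modules."""


class FluorbindError(Exception):
    """Base class for all errors raised by fluorbind."""


class FormatError(FluorbindError, ValueError):
    """A spectrum file could not be parsed (malformed header or table)."""


class ValidationError(FluorbindError, ValueError):
    """A spectral object violates one of its invariants."""


class InsufficientDataError(FluorbindError, ValueError):
    """Too few usable points remain to perform a fit."""


class RangeError(FluorbindError, ValueError):
    """A requested wavelength window falls outside the available data."""


class DomainError(FluorbindError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""
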