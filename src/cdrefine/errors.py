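"""Exception hierarchy.

All package errors derive from :class:`CDRefineError` so callers can catch
one base class; subtypes distinguish parse, validation, contract (caller
misuse), and range failures.
"""


class CDRefineError(Exception):
    """Base class for all cdrefine errors."""


class ParseError(CDRefineError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(CDRefineError):
    """Data violates a documented invariant."""


class ContractError(CDRefineError):
    """An operation was called with arguments violating its precondition."""


class RangeError(CDRefineError):
    """A wavelength or window lies outside the available data span."""


class DegenerateFitError(CDRefineError):
    """A fit produced all-zero weights where fractions were requested."""


class MappingError(CDRefineError):
    """A secondary-structure code has no entry in the mapping table."""


class AnnotationError(CDRefineError):
    """A donor/acceptor annotation is incomplete (e.g. donor without H)."""


class UndefinedStatisticError(CDRefineError):
    """A statistic (e.g. Pearson r on constant input) is undefined."""
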