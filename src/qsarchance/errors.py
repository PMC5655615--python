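"""Exception hierarchy.

Contract violations (bad arguments, empty inputs) raise :class:`ContractError`;
malformed files raise :class:`FormatError` or :class:`ParseError`; bad
configuration (missing columns, infeasible plans) raises :class:`ConfigError`;
mathematically invalid inputs raise :class:`DomainError`; failed model fits
raise :class:`FitError`.
"""


class QsarChanceError(Exception):
    """Base class for all errors raised by this package."""


class ContractError(QsarChanceError, ValueError):
    """An argument violates an operation's precondition."""


class FormatError(QsarChanceError, ValueError):
    """A file's structure is malformed (duplicate headers, bad SDF layout)."""


class ParseError(FormatError):
    """A cell or value could not be parsed; message names row and column."""


class ConfigError(QsarChanceError, ValueError):
    """A plan or configuration is inconsistent with the data it targets."""


class DomainError(QsarChanceError, ValueError):
    """A numeric input lies outside the mathematical domain of an operation."""


class FitError(QsarChanceError, RuntimeError):
    """A model fit failed (rank deficiency, degenerate design)."""


class EmptyPoolError(QsarChanceError, RuntimeError):
    """Descriptor-pool reduction removed every descriptor."""
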