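"""Exception hierarchy shared by all modules.

Every error raised by the library derives from :class:`McdaError`, so callers
(and the CLI) can catch one type and report a single-line message.
"""


class McdaError(Exception):
    """Base class for all errors raised by this package."""


class StructuralError(McdaError):
    """Input has the wrong shape (non-square grid, dimension mismatch, ragged rows)."""


class DomainError(McdaError):
    """A value violates the mathematical domain (non-positive judgment, zero weight)."""


class ReciprocityError(McdaError):
    """A pairwise judgment and its mirror entry are not reciprocals within tolerance."""


class ScaleError(McdaError):
    """A pairwise judgment lies outside the Saaty 1/9..9 scale (when configured as an error)."""


class ConfigurationError(McdaError):
    """A configuration value is unusable (unknown random-index order, empty score range)."""


class ReconciliationError(McdaError):
    """Criterion sets of the pairwise and decision matrices cannot be matched by id."""


class ParseError(McdaError):
    """A CSV file could not be parsed; the message carries row/column coordinates."""
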