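"""Exception hierarchy.

User-facing errors (bad inputs, malformed files, degenerate data) derive
from :class:`BarnicheUserError` so the CLI can map them to exit code 1;
anything else is treated as an internal error (exit code 2).
"""


class BarnicheError(Exception):
    """Base class for all package errors."""


class BarnicheUserError(BarnicheError):
    """Errors attributable to user input or data."""


class InvalidSpecError(BarnicheUserError):
    """A generator or configuration specification is invalid."""


class InvalidInputError(BarnicheUserError):
    """An argument violates a documented precondition."""


class FormatError(BarnicheUserError):
    """A file does not conform to its expected dialect."""


class MismatchError(BarnicheUserError):
    """Two inputs that must align (tree tips vs. matrix rows, frames) do not."""


class NoHabitatError(BarnicheUserError):
    """No (or not enough) grid cells satisfy a species' niche intervals."""


class LowRecordError(BarnicheUserError):
    """Too few occurrence records to fit a suitability surface."""


class EmptySpeciesError(BarnicheUserError):
    """Validation removed every occurrence of a species."""


class CodingError(BarnicheUserError):
    """Binned-range coding is impossible (occupied range outside scheme)."""
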