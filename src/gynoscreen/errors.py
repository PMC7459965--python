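"""Exception hierarchy.

All package errors derive from :class:`GynoscreenError` so callers can catch
one base class; the subclasses distinguish malformed files, impossible
experimental designs, bad data values, and misuse of the API.
"""


class GynoscreenError(Exception):
    """Base class for all errors raised by gynoscreen."""


class FormatError(GynoscreenError):
    """A file does not conform to the expected tabular format."""


class DesignError(GynoscreenError):
    """The sample layout violates the female x condition design."""


class DataError(GynoscreenError):
    """Values are inconsistent (e.g. more survivors than eggs)."""


class NormalizationError(GynoscreenError):
    """Size factors cannot be estimated (empty reference set)."""


class UsageError(GynoscreenError):
    """An operation was called with invalid arguments."""
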