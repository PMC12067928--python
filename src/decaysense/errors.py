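"""Exception hierarchy for the package.

All domain errors derive from :class:`DecaySenseError` so callers can catch
pipeline failures with a single except clause while still distinguishing
schema problems from numerical ones.
"""


class DecaySenseError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DecaySenseError):
    """A required column could not be resolved in an input file."""


class PlateFormatError(DecaySenseError):
    """A plate file violates the trace contract (e.g. duplicate times in a well)."""


class MetadataError(DecaySenseError):
    """Sample metadata is malformed (duplicate ids, empty group labels)."""


class FitInputError(DecaySenseError):
    """A trace cannot be fitted (too short, non-finite values)."""


class NonIdentifiableTraceError(DecaySenseError):
    """A flat trace carries no decay information; the rate is not identifiable."""


class BatchModelError(DecaySenseError):
    """A batch lacks the anchor groups needed to estimate its baseline."""
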