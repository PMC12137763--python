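"""Exception hierarchy for the T2* pipeline.

All pipeline errors derive from :class:`RatError` so callers (and the CLI)
can catch the whole family with one clause.
"""


class RatError(Exception):
    """Base class for all pipeline errors."""


class FormatError(RatError):
    """A file is not in the expected format (e.g. not a 4D NIfTI)."""


class MetadataError(RatError):
    """Acquisition metadata is inconsistent with the data (e.g. echo count)."""


class AlignmentError(RatError):
    """Two grids that must share a voxel grid do not."""


class SchemaError(RatError):
    """A tabular input is missing required columns."""


class EmptyInputError(RatError):
    """An input contained no usable records."""


class DegenerateInputError(RatError):
    """A fit cannot be performed (rank-deficient design, no spread)."""


class InsufficientDataError(RatError):
    """Fewer observations than the operation requires."""


class PhantomSpecError(RatError):
    """A synthetic phantom specification is internally inconsistent."""
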