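"""Exception hierarchy for the xflux pipeline.

Every error raised by the package derives from :class:`XfluxError` so batch
drivers (the CLI, user scripts) can catch one type and still report the
specific failure mode.
"""


class XfluxError(Exception):
    """Base class for all xflux errors."""


class MalformedGroupError(XfluxError):
    """A Wave Group label does not follow the ``"<exp_group> <ASSAY>"`` convention."""


class SchemaError(XfluxError):
    """An input file is missing required columns or violates structural invariants."""


class EmptyFileError(XfluxError):
    """A rate file contains no data rows."""


class EmptyDirectoryError(XfluxError):
    """A rate directory contains no readable rate files."""


class PlateCollisionError(XfluxError):
    """Two input files resolve to the same plate identifier."""


class CoverageError(XfluxError):
    """A normalization table does not cover every well in the rate table."""


class ValidationError(XfluxError):
    """A configuration or table value violates its declared constraints."""


class StateError(XfluxError):
    """An operation was applied in an invalid object state (e.g. double normalization)."""


class LayoutError(XfluxError):
    """The measurement count does not fit the default partition layout."""


class MissingAssayError(XfluxError):
    """A partition scheme references an assay type absent from the data."""


class MissingStateError(XfluxError):
    """A well lacks an energetic state required for a calculation."""


class EmptyGroupError(XfluxError):
    """A summarizer received no finite values."""
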