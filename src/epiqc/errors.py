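"""Exception hierarchy for epiqc.

All package-specific failures derive from :class:`QCError` so callers can
catch one type at the CLI boundary.
"""


class QCError(Exception):
    """Base class for all epiqc errors."""


class DimensionalityError(QCError):
    """Image does not have the required number of dimensions."""


class FormatError(QCError):
    """A file could not be parsed in the expected format."""


class LengthMismatchError(QCError):
    """Row/volume counts of paired inputs disagree."""


class VocabularyError(QCError):
    """A label or keyword falls outside the allowed vocabulary."""


class DuplicationError(QCError):
    """A (subject, rater) cell was supplied more than once."""


class GeometryError(QCError):
    """Spatial shapes or geometric parameters are inconsistent."""


class InsufficientDataError(QCError):
    """Not enough volumes/subjects/voxels to compute the quantity."""


class EmptyMaskError(QCError):
    """The brain mask contains no voxels."""


class ConfigurationError(QCError):
    """A required configuration entry is missing or invalid."""


class IncompleteInputError(QCError):
    """A classification was requested with required inputs missing."""


class UndefinedStatisticError(QCError):
    """The requested agreement statistic is undefined for this table."""
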