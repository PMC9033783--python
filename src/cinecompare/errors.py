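"""Exception hierarchy.

Every failure mode that callers are expected to handle gets its own class;
all inherit from :class:`CineCompareError` so batch drivers can catch one
type.
"""


class CineCompareError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(CineCompareError):
    """A contour's geometry is invalid and could not be repaired."""


class UndefinedMetricError(CineCompareError):
    """A metric has no defined value for the given inputs (e.g. Hausdorff
    distance of an empty contour). Callers record a missing value."""


class ConfigurationError(CineCompareError):
    """A configuration value is out of its admissible range."""


class AmbiguityError(CineCompareError):
    """Two images claim the same (slice, phase) cell of a cine grid."""


class MissingStructureError(CineCompareError):
    """A requested cardiac structure has no contours anywhere in the case."""


class ComparabilityError(CineCompareError):
    """Two cases do not reference the same image set and cannot be compared."""


class VocabularyError(CineCompareError):
    """An annotation uses a contour name outside the configured vocabulary."""


class AnnotationFormatError(CineCompareError):
    """An annotation file is malformed (bad WKT, wrong version, ...)."""


class DicomTagError(CineCompareError):
    """A DICOM file lacks a tag that is mandatory for geometry handling."""
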