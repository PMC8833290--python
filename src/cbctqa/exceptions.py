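"""Exception hierarchy for the QA pipeline.

All package errors derive from :class:`QAError` so callers can catch one type.
"""


class QAError(Exception):
    """Base class for all cbctqa errors."""


class FormatError(QAError):
    """Malformed or inconsistent file metadata (names the offending attribute)."""


class GeometryError(QAError):
    """Inconsistent spatial metadata, e.g. non-uniform slice spacing."""


class BoundsError(QAError):
    """A ROI or index falls outside the volume."""


class SpecError(QAError):
    """Invalid phantom/simulation specification (e.g. insert outside the disk)."""


class AlignmentError(QAError):
    """Calibration records do not share a common angle grid."""


class DetectionError(QAError):
    """Feature detection failed (too few rods, no edge found, ...)."""


class MatchingError(QAError):
    """Ambiguous rod-to-nominal distance matching (degenerate layout)."""


class DegenerateFitError(QAError):
    """A regression cannot be fitted (e.g. identical nominal CT-numbers)."""


class ProfileError(QAError):
    """The masked uniformity profile is too short to evaluate."""


class UndefinedCNRError(QAError):
    """CNR undefined because both noise estimates are zero."""


class PlacementError(QAError):
    """No ROI of the requested size fits inside the mask."""


class FitError(QAError):
    """Non-linear model fit failed after deterministic restarts."""


class SchemaError(QAError):
    """A tabular input is missing required rows or columns."""


class CollisionError(QAError):
    """Duplicate protocol/metric pair supplied to the report assembler."""
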