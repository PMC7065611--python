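"""Exception hierarchy for the stainscan pipeline.

Every stage raises a subclass of :class:`StainScanError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class StainScanError(Exception):
    """Base class for all stainscan errors."""


class ProtocolError(StainScanError):
    """Invalid acquisition protocol (bad filter grid, bad intensities)."""


class GeometryError(StainScanError):
    """A region or stain does not fit where it must (out of bounds, too big)."""


class FormatError(StainScanError):
    """An image file has the wrong dimensions or bit depth."""


class ManifestError(StainScanError):
    """A channel manifest is malformed (duplicate channels, missing columns)."""


class ChannelLookupError(StainScanError):
    """Zero or multiple channels match a (light, filter) query."""


class ComparisonError(StainScanError):
    """Two frames or feature sets being compared are not comparable."""


class ParameterError(StainScanError):
    """A numeric parameter is outside its valid range."""


class DegenerateInputError(StainScanError):
    """The input has too little structure for the requested operation."""


class TrainingError(StainScanError):
    """Classifier training input is unusable (single class, too few points)."""


class InputError(StainScanError):
    """A measured value is invalid (negative ATP/TPC, missing assay)."""


class DataQualityWarning(UserWarning):
    """Recoverable inconsistency in tabular input (rounding, area mismatch)."""
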