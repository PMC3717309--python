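"""Exception hierarchy for the qdmi package."""


class QdmiError(Exception):
    """Base class for all qdmi errors."""


class ConfigurationError(QdmiError):
    """A required channel, key or parameter is missing or invalid."""


class FormatError(QdmiError):
    """An input file does not have the expected structure."""


class PlacementError(QdmiError):
    """Phantom nuclei could not be packed into the requested field."""


class SegmentationError(QdmiError):
    """Segmentation preconditions violated (e.g. constant image, seed outside mask)."""


class FitError(QdmiError):
    """A model fit failed to converge after all restarts."""
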