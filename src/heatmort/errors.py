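"""Exception types shared across the pipeline."""


class HeatmortError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HeatmortError):
    """A generator or run specification is invalid."""


class DegenerateInputError(HeatmortError):
    """Too few, or collinear, samples for a fit to be meaningful."""


class NonIdentifiableError(HeatmortError):
    """A regression slope is (numerically) zero, so its x-intercept is undefined."""


class DataQualityError(HeatmortError):
    """Gridded input fails a completeness check.

    ``cells`` lists the offending (lat_index, lon_index) pairs.
    """

    def __init__(self, message: str, cells=None):
        super().__init__(message)
        self.cells = list(cells) if cells is not None else []


class AlignmentError(HeatmortError):
    """Gridded inputs do not share a common grid."""


class MaskError(HeatmortError):
    """A populated cell has no region assignment."""
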