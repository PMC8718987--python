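"""Exception hierarchy shared across the package."""


class NRPError(Exception):
    """Base class for all package errors."""


class FormatError(NRPError):
    """Unreadable or unsupported image format."""


class DimensionError(NRPError):
    """Zero-sized image, out-of-bounds ROI, or mismatched shapes."""


class StateError(NRPError):
    """Operation applied to an object in the wrong state (e.g. double inversion)."""


class ParameterError(NRPError):
    """Invalid parameter value for an operation."""


class DataError(NRPError):
    """Invalid data values (non-positive protein, non-finite densities...)."""


class InsufficientDataError(NRPError):
    """Too few levels, replicates or observations for the requested statistic."""


class DegenerateModelError(NRPError):
    """Model unusable for the requested operation (zero slope, zero variance)."""


class GeometryError(NRPError):
    """ROI geometry violates the analysis contract (e.g. straddles the midline)."""


class JustificationError(NRPError):
    """Protein correction requested for samples failing the dispersion rule."""
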