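"""Exception hierarchy shared across the package."""


class FtirlipError(Exception):
    """Base class for all package errors."""


class SpectraFormatError(FtirlipError):
    """A spectra table could not be parsed (bad header, ragged rows...)."""


class MetadataError(FtirlipError):
    """Sample metadata is missing, unparseable, or violates uniqueness."""


class GridError(FtirlipError):
    """The wavenumber grid violates an assumption (non-uniform, too short)."""


class EmptySelectionError(FtirlipError):
    """A wavenumber region selects no grid points."""


class DegenerateSampleError(FtirlipError):
    """A per-sample fit is degenerate (e.g. EMSC multiplicative term ~ 0)."""


class CatalogueError(FtirlipError):
    """A fatty acid id has no descriptor in the catalogue."""


class ResponseError(FtirlipError):
    """A regression response is missing or degenerate."""


class SegmentationError(FtirlipError):
    """Cross-validation segments are unusable (single day, empty fold)."""
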