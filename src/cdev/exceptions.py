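"""Exception hierarchy shared across the package."""


class CdevError(Exception):
    """Base class for all package-specific errors."""


class ShapeMismatchError(CdevError):
    """Two matrices do not share shape and/or gene/sample identifiers."""


class DegenerateInputError(CdevError):
    """Input is structurally valid but numerically unusable (all-zero
    matrix, zero/infinite scaling ratios, log-scale values, ...)."""


class DegenerateReferenceError(CdevError):
    """A reference set whose per-sample count sum vanishes in some sample."""


class InsufficientOverlapError(CdevError):
    """Too few genes shared (positive) between a sample and the TMM
    reference sample to form a trimmed mean."""


class InsufficientGenesError(CdevError):
    """An iterative normalizer shrank its retained gene set below the
    minimum needed for stable factors."""


class EmptyRetainedSetError(CdevError):
    """Every gene was flagged differential; no gene left to normalize on."""


class InsufficientReferencesError(CdevError):
    """No spike-in / reference candidate survives the detection threshold."""
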