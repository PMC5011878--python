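"""Exception hierarchy shared across the pipeline."""


class RhizoslidesError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RhizoslidesError, ValueError):
    """An input table is missing required columns or has malformed fields."""


class IntegrityError(RhizoslidesError, ValueError):
    """Records violate a design invariant (duplicate keys, conflicting values,
    dangling references)."""


class ShapeMismatchError(RhizoslidesError, ValueError):
    """Two rasters that must be pixel-aligned have different dimensions."""


class MetadataError(RhizoslidesError, ValueError):
    """Raster metadata (e.g. mm-per-pixel scale) disagrees between inputs."""


class DegenerateHistogramError(RhizoslidesError, ValueError):
    """A histogram-based threshold cannot be chosen (constant feature map)."""


class ZoneUndefinedError(RhizoslidesError, ValueError):
    """Branching zone has no proximal anchor (no lateral at solution change)."""


class ZoneEmptyError(RhizoslidesError, ValueError):
    """Branching zone has non-positive extent (no new distal lateral)."""


class InsufficientDataError(RhizoslidesError, ValueError):
    """Too few observations for the requested fit or reduction."""


class SingularFitError(RhizoslidesError, ValueError):
    """Design degenerate for the requested fit (e.g. all time values equal)."""


class ConvergenceError(RhizoslidesError, RuntimeError):
    """Iterative estimation failed to converge within the iteration budget."""


class RootLookupError(RhizoslidesError, KeyError):
    """A root id was not found in any supplied root system."""
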