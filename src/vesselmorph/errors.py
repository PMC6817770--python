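"""Exception hierarchy shared across the package."""


class VesselMorphError(Exception):
    """Base class for all package errors."""


class GeometryError(VesselMorphError):
    """A synthetic vessel does not fit the requested raster, or its
    boundary construction is invalid (self-intersecting / non-positive)."""


class MaskFormatError(VesselMorphError):
    """A raster or sidecar file violates the 3-label mask contract."""


class MaskValidationError(VesselMorphError):
    """A decoded mask fails the semantic invariants of a vessel
    cross-section (missing lumen/wall, fragmented lumen, border contact)."""


class MeasurementError(VesselMorphError):
    """A morphometric estimator cannot produce a value for this mask."""


class ExcludedRecordError(VesselMorphError):
    """A classifier was asked to label a record that the exclusion
    filter has already removed from the analysis."""


class DomainError(VesselMorphError):
    """Arguments outside the mathematical domain of an operation
    (empty sample, non-positive area, empty restricted subgroup...)."""
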