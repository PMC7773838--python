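"""Exception hierarchy for the hipdx pipeline."""


class HipdxError(Exception):
    """Base class for all hipdx errors."""


class DegenerateGeometryError(HipdxError):
    """Zero-length vector, coincident points, or otherwise degenerate geometry."""


class CollinearityError(DegenerateGeometryError):
    """Three points that are collinear (or coincident) where a circle is required."""


class AnnotationSchemaError(HipdxError):
    """Annotation file fails schema validation or a domain invariant."""


class LandmarkError(HipdxError):
    """An automatic landmark could not be constructed from the delineation."""


class InputError(HipdxError):
    """Invalid input to a statistical operation (e.g. too few samples)."""


class ConfigError(HipdxError):
    """Invalid simulation or run configuration."""


class ConstructionError(HipdxError):
    """Synthetic pelvis construction infeasible for the requested angles."""


class DegenerateModelError(HipdxError):
    """Covariance matrix is singular or not positive definite."""


class ModelSchemaError(HipdxError):
    """Serialized model file is malformed."""
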