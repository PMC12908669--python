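"""Exception hierarchy.

Every rejection the converter can produce maps to one subclass so callers
(CLI, batch pipeline) can report dispositions without string matching.
"""


class MidsError(Exception):
    """Base class for all package errors."""


class FilenameError(MidsError):
    """Filename does not follow the entity grammar."""


class PairingError(MidsError):
    """Suffix and modality folder do not belong together."""


class EmptyInputError(MidsError):
    """No readable DICOM input found."""


class GeometryError(MidsError):
    """Frame geometry is missing or inconsistent."""


class NonUniformSpacingError(GeometryError):
    """Slice gaps vary by more than the tolerated ratio."""


class DegenerateGeometryError(GeometryError):
    """Through-plane direction cannot be determined (single slice, no thickness)."""


class InvalidRescaleError(MidsError):
    """Rescale slope of zero."""


class AmbiguousPartError(MidsError):
    """Complex-part tokens in one series cannot be disambiguated."""


class RaggedAcquisitionError(MidsError):
    """Echoes carry unequal slice counts."""


class DuplicateFrameError(MidsError):
    """Two frames share the same (echo, position)."""


class UnscalablePhaseError(MidsError):
    """Constant phase plane outside [-pi, pi]; no range to map."""


class AmbiguousDetectionError(MidsError):
    """More than one converter matched at equal specificity."""


class IncompleteMetadataError(MidsError):
    """A required sidecar field could not be extracted; series rejected."""

    def __init__(self, field: str, suffix: str):
        self.field = field
        self.suffix = suffix
        super().__init__(f"required field {field!r} unobtainable for suffix {suffix!r}")


class CollisionError(MidsError):
    """Output file exists and overwrite is disabled."""


class NotFoundError(MidsError):
    """Requested entity not present in the dataset index."""


class RoundTripError(MidsError):
    """DICOM reconstruction impossible (missing extra sidecar, shape mismatch)."""


class ShapeMismatchError(RoundTripError):
    """Voxel shape inconsistent with the stored frame geometry."""
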