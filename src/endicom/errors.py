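"""Exception hierarchy.

Every failure mode raised by this package derives from :class:`EndicomError`
so callers (and the CLI) can distinguish domain errors from programming
errors.
"""


class EndicomError(Exception):
    """Base class for all errors raised by endicom."""


class GeometryError(EndicomError):
    """Invalid or inconsistent volume geometry (bad directions, spacing, gaps)."""


class OutOfVolumeError(EndicomError, ValueError):
    """A patient-frame point maps outside the volume's voxel lattice.

    Carries the offending point in ``.point`` (mm, patient frame).
    """

    def __init__(self, message, point=None):
        super().__init__(message)
        self.point = point


class SeriesFormatError(EndicomError):
    """A DICOM series is unreadable or missing required attributes."""


class SeriesAmbiguityError(SeriesFormatError):
    """A directory mixes files from more than one series."""


class EncodingRangeError(EndicomError):
    """An HU value cannot be represented at the volume's declared bit depth."""


class SeparabilityError(EndicomError):
    """Native intensities overlap the sentinel band; thresholding could not
    distinguish marks from anatomy."""


class CollisionError(EndicomError):
    """Two landmark points map to the same voxel under an error-on-collision policy."""


class InsufficientDataError(EndicomError, ValueError):
    """Fewer point pairs than a rigid transform requires."""


class DegenerateFiducialsError(EndicomError, ValueError):
    """Fiducial configuration is collinear or otherwise rank-deficient."""


class FrameError(EndicomError):
    """A point cloud is in the wrong coordinate frame for the operation."""


class UnknownSequenceError(EndicomError, KeyError):
    """A histology result refers to a sequence number absent from the cloud."""


class PhantomSpecError(EndicomError, ValueError):
    """A phantom specification cannot be rasterized on the requested grid."""
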