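"""Exception hierarchy.

Every error raised by the library derives from :class:`VoxflapError`, so callers
(and the CLI) can catch one type at the pipeline boundary.
"""


class VoxflapError(Exception):
    """Base class for all voxflap errors."""


class VolumeFormatError(VoxflapError):
    """Malformed or internally inconsistent volume input (e.g. a heterogeneous
    DICOM series)."""


class UnsupportedInputError(VoxflapError):
    """Structurally valid input the library does not handle (4D images,
    oblique orientations, non-scalar data)."""


class GeometryError(VoxflapError):
    """Geometric precondition violated: non-watertight mesh, mismatched grids,
    degenerate struts."""


class ConfigurationError(VoxflapError):
    """Invalid configuration value or reference to an undeclared channel."""


class EmptyROIError(VoxflapError):
    """A sampling region of interest contains no voxels."""


class EmptySurfaceError(VoxflapError):
    """Isosurface extraction requested from a channel with empty support."""


class ResolutionError(VoxflapError):
    """Requested features are too fine for the working voxel size."""
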