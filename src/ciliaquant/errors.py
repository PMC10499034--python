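"""Exception types shared across the package."""


class CiliaQuantError(Exception):
    """Base class for package-specific errors."""


class InvalidInputError(CiliaQuantError, ValueError):
    """Input violates an operation's precondition (empty image, bad shape)."""


class InvalidParameterError(CiliaQuantError, ValueError):
    """A parameter is outside its allowed range."""


class DegenerateImageError(CiliaQuantError, ValueError):
    """The image cannot be thresholded (e.g. constant intensity).

    Raised instead of silently returning an all-false mask so that
    pipelines can apply their own exclusion rules.
    """


class AnisotropyError(CiliaQuantError, ValueError):
    """Voxel anisotropy prevents an operation (reslicing needs cubic voxels)."""


class BoundsError(CiliaQuantError, ValueError):
    """An ROI does not fit inside the image it is applied to."""


class GeometryError(CiliaQuantError, ValueError):
    """Simulated geometry does not fit the requested stack."""


class PackingError(CiliaQuantError, RuntimeError):
    """Non-overlapping object placement failed after bounded retries."""


class UndefinedStatisticError(CiliaQuantError, ValueError):
    """A ratio or statistic is undefined for the given data."""
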