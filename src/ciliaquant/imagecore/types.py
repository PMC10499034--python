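"""Calibrated image containers and ROI geometry.

Conventions: coordinates are 0-based, arrays are indexed (z, y, x) (with a
leading channel axis for multi-channel stacks), pixel centers sit at integer
coordinates, and micrometre-to-pixel conversion rounds half up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from ..errors import InvalidInputError, InvalidParameterError


def um_to_px(value_um: float, pixel_size_um: float) -> int:
    """Convert a physical length to pixels, rounding half up."""
    return int(math.floor(value_um / pixel_size_um + 0.5))


@dataclass(frozen=True)
class Calibration:
    """Physical voxel calibration in micrometres.

    Attributes
    ----------
    pixel_size_xy : float
        Lateral size of one pixel (µm).
    z_step : float
        Axial spacing between consecutive z-slices (µm).
    """

    pixel_size_xy: float
    z_step: float

    def __post_init__(self) -> None:
        if not (self.pixel_size_xy > 0 and self.z_step > 0):
            raise InvalidParameterError(
                f"calibration must be positive, got pixel_size_xy="
                f"{self.pixel_size_xy}, z_step={self.z_step}"
            )

    @property
    def is_isotropic(self) -> bool:
        return math.isclose(self.pixel_size_xy, self.z_step, rel_tol=1e-9)


@dataclass
class ImageStack:
    """A calibrated multi-channel 3D intensity volume, indexed (c, z, y, x)."""

    voxels: np.ndarray
    channel_names: Sequence[str]
    calibration: Calibration
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise InvalidInputError(
                f"voxels must be (channel, z, y, x), got shape {self.voxels.shape}"
            )
        if len(self.channel_names) != self.voxels.shape[0]:
            raise InvalidInputError("channel_names length must match channel axis")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise InvalidInputError("channel_names must be unique")
        if self.bit_depth not in (8, 16):
            raise InvalidParameterError("bit_depth must be 8 or 16")
        if self.voxels.size and (
            self.voxels.min() < 0 or self.voxels.max() > 2**self.bit_depth - 1
        ):
            raise InvalidInputError(
                f"intensities must lie in [0, {2**self.bit_depth - 1}]"
            )

    @property
    def shape_zyx(self) -> Tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) volume of one named channel."""
        try:
            idx = list(self.channel_names).index(name)
        except ValueError:
            raise InvalidInputError(
                f"channel {name!r} not in {list(self.channel_names)}"
            ) from None
        return self.voxels[idx]


@dataclass
class BinaryMask:
    """A boolean mask, 2D or 3D, with the threshold that produced it.

    ``threshold_value`` is None for masks constructed directly (not by
    thresholding).  ``warning`` carries non-fatal diagnostics, e.g. the
    MinError(I) mean-threshold fallback.
    """

    pixels: np.ndarray
    calibration: Optional[Calibration] = None
    threshold_value: Optional[float] = None
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim not in (2, 3):
            raise InvalidInputError("mask must be 2D or 3D")


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangular ROI.

    ``center`` is (x, y); its unit is micrometres when ``unit == "um"``,
    pixels when ``unit == "px"``.  ``width`` and ``height`` are always in
    micrometres.
    """

    center: Tuple[float, float]
    width: float
    height: float
    unit: str = "um"

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise InvalidParameterError("ROI width and height must be positive")
        if self.unit not in ("um", "px"):
            raise InvalidParameterError("unit must be 'um' or 'px'")

    def center_px(self, calibration: Calibration) -> Tuple[int, int]:
        cx, cy = self.center
        if self.unit == "um":
            return (
                um_to_px(cx, calibration.pixel_size_xy),
                um_to_px(cy, calibration.pixel_size_xy),
            )
        return int(round(cx)), int(round(cy))

    def size_px(self, calibration: Calibration) -> Tuple[int, int]:
        """(width_px, height_px), rounded half up."""
        return (
            um_to_px(self.width, calibration.pixel_size_xy),
            um_to_px(self.height, calibration.pixel_size_xy),
        )


@dataclass(frozen=True)
class PolyROI:
    """Closed simple polygon ROI with vertices as ordered (x, y) pixel pairs."""

    vertices: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", tuple(map(tuple, self.vertices)))
        if len(self.vertices) < 3:
            raise InvalidParameterError("polygon needs at least 3 vertices")
        if not _ShapelyPolygon(self.vertices).is_simple:
            raise InvalidParameterError("polygon must be simple (non-self-intersecting)")

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        """Rasterize to a boolean mask of the given (rows, cols) shape."""
        from skimage.draw import polygon as _sk_polygon

        rows = [v[1] for v in self.vertices]
        cols = [v[0] for v in self.vertices]
        rr, cc = _sk_polygon(rows, cols, shape=shape)
        out = np.zeros(shape, dtype=bool)
        out[rr, cc] = True
        return out


@dataclass
class Particle:
    """One 8-connected component from particle analysis."""

    pixel_indices: frozenset  # of (y, x) tuples
    area_px: int
    perimeter_px: float
    circularity: float
    centroid: Tuple[float, float]  # (x, y)
    touches_edge: bool
    pixel_size_xy: Optional[float] = None
    area_um2: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if self.pixel_size_xy is not None and self.area_um2 is None:
            self.area_um2 = self.area_px * self.pixel_size_xy**2
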