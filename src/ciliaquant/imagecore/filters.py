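"""Intensity-image primitives: smoothing, projection, background subtraction,
reslicing, and ROI cropping.

These reproduce the behaviour of the corresponding FIJI commands at the level
of their effect on the data (not bit-for-bit): Smooth is a 3×3 in-plane mean
with edge truncation, and Subtract Background is a rolling-ball (grayscale
opening with a ball-height structuring function, after Sternberg 1983), with
shrink/upsample acceleration for large radii.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from ..errors import (
    AnisotropyError,
    BoundsError,
    InvalidInputError,
    InvalidParameterError,
)
from .types import Calibration, RectROI


def smooth(image: np.ndarray) -> np.ndarray:
    """3×3 neighborhood mean, edge pixels averaging in-bounds neighbors only.

    3D inputs are smoothed slice-wise in-plane.  Returns float64.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise InvalidInputError("cannot smooth an empty image")
    if image.ndim == 3:
        return np.stack([smooth(sl) for sl in image])
    if image.ndim != 2:
        raise InvalidInputError("smooth expects a 2D or 3D image")
    kernel = np.ones((3, 3))
    sums = ndi.correlate(image, kernel, mode="constant", cval=0.0)
    counts = ndi.correlate(np.ones_like(image), kernel, mode="constant", cval=0.0)
    return sums / counts


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum intensity projection of a (z, y, x) stack along z."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise InvalidInputError("max_project expects a (z, y, x) stack with ≥1 slice")
    return stack.max(axis=0)


def _ball_structure(radius: float) -> np.ndarray:
    """Ball-height structuring function; -inf outside the ball's footprint."""
    r = int(math.ceil(radius))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = (x.astype(float)) ** 2 + (y.astype(float)) ** 2
    h = np.full(d2.shape, -np.inf)
    inside = d2 <= radius**2
    h[inside] = np.sqrt(radius**2 - d2[inside]) - radius
    return h


def _rolling_ball_background(image: np.ndarray, radius: float) -> np.ndarray:
    ball = _ball_structure(radius)
    eroded = ndi.grey_erosion(image, structure=ball, mode="reflect")
    return ndi.grey_dilation(eroded, structure=ball, mode="reflect")


def rolling_ball_subtract(image: np.ndarray, radius_px: int) -> np.ndarray:
    """Subtract the background estimated by rolling a ball under the surface.

    For radii above 16 px the image is min-pooled by an integer shrink
    factor, the ball rolled on the reduced image with a proportionally
    reduced radius, and the background bilinearly upsampled — the classic
    acceleration for large structuring elements.  Output is clipped at 0.
    """
    if radius_px < 1:
        raise InvalidParameterError("rolling-ball radius must be ≥ 1 px")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise InvalidInputError("rolling_ball_subtract expects a non-empty 2D image")

    shrink = max(1, int(radius_px) // 16)
    if shrink == 1:
        background = _rolling_ball_background(image, float(radius_px))
    else:
        ny, nx = image.shape
        py = (-ny) % shrink
        px = (-nx) % shrink
        padded = np.pad(image, ((0, py), (0, px)), mode="edge")
        blocks = padded.reshape(
            padded.shape[0] // shrink, shrink, padded.shape[1] // shrink, shrink
        )
        small = blocks.min(axis=(1, 3))
        small_bg = _rolling_ball_background(small, radius_px / shrink)
        background = ndi.zoom(small_bg, shrink, order=1, mode="nearest", grid_mode=True)
        background = background[:ny, :nx]
        # upsampling can overshoot the surface locally; the ball never does
        background = np.minimum(background, image)
    return np.clip(image - background, 0.0, None)


def reslice_side_view(
    stack: np.ndarray,
    calibration: Optional[Calibration] = None,
    inverse: bool = False,
) -> np.ndarray:
    """Re-index a (z, y, x) stack into side-view slices.

    Forward: output[y] is a (z, x) image whose top row is the highest
    (apical) z-slice: out[y, r, x] = in[Z-1-r, y, x].  ``inverse=True``
    undoes the forward transform exactly.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise InvalidInputError("reslice expects a 3D (z, y, x) stack")
    if calibration is not None and not calibration.is_isotropic:
        raise AnisotropyError(
            "side-view reslicing requires pixel_size_xy == z_step "
            f"(got {calibration.pixel_size_xy} vs {calibration.z_step}); "
            "resampling anisotropic stacks is out of scope"
        )
    if inverse:
        # in: (y, r, x) with r = Z-1-z  ->  out[z, y, x] = in[y, Z-1-z, x]
        return np.swapaxes(stack[:, ::-1, :], 0, 1).copy()
    return np.swapaxes(stack, 0, 1)[:, ::-1, :].copy()


def crop_roi(
    image: np.ndarray, roi: RectROI, calibration: Calibration
) -> np.ndarray:
    """Crop an axis-aligned rectangular ROI from a 2D image or (z, y, x) stack.

    The ROI center and size are converted to pixels (rounding half up); the
    resulting window must lie fully inside the image.
    """
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise InvalidInputError("crop_roi expects a 2D image or 3D stack")
    ny, nx = image.shape[-2:]
    cx, cy = roi.center_px(calibration)
    w, h = roi.size_px(calibration)
    x0 = cx - w // 2
    y0 = cy - h // 2
    x1, y1 = x0 + w, y0 + h
    if x0 < 0 or y0 < 0 or x1 > nx or y1 > ny:
        raise BoundsError(
            f"ROI [{x0}:{x1}, {y0}:{y1}] px exceeds image bounds ({ny}, {nx})"
        )
    return image[..., y0:y1, x0:x1]
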